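"""Greedy longest-match dictionary tagger.

A deliberately simple baseline that turns raw text into entity spans so
the extraction pipeline runs end-to-end without a trained recognizer.
Longest-match mirrors the maximize-coverage annotation principle: in
左手小指疼痛, 手小指 (the whole progressive position) beats the shorter
手.  Output spans never overlap by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

from .schema import Entity, EntityType


@dataclass(frozen=True)
class TypedDictionary:
    """Surface string -> entity type; a surface maps to exactly one type."""

    entries: Mapping[str, EntityType]
    max_len: int

    @classmethod
    def from_entries(cls, entries: Mapping[str, EntityType]) -> "TypedDictionary":
        if not entries:
            raise ValueError("dictionary must be nonempty")
        return cls(dict(entries), max(len(s) for s in entries))

    @classmethod
    def from_lexicon(
        cls, lexicon: Mapping[EntityType, Iterable[str]]
    ) -> "TypedDictionary":
        """Build from a typed lexicon, rejecting surface conflicts."""
        entries: dict[str, EntityType] = {}
        for etype, surfaces in lexicon.items():
            for s in surfaces:
                if s in entries and entries[s] is not etype:
                    raise ValueError(
                        f"surface {s!r} maps to both {entries[s].value} and {etype.value}"
                    )
                entries[s] = etype
        return cls.from_entries(entries)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "TypedDictionary":
        """Load ``label<TAB>surface`` lines."""
        lex: dict[EntityType, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    label, surface = line.split("\t")
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno} is not label<TAB>surface") from exc
                lex.setdefault(EntityType(label), []).append(surface)
        return cls.from_lexicon(lex)


def longest_match_tag(text: str, dictionary: TypedDictionary) -> list[Entity]:
    """Left-to-right greedy scan: at each position take the longest
    dictionary match, emit it, advance past it; unmatched characters
    are skipped."""
    out: list[Entity] = []
    i, n = 0, len(text)
    while i < n:
        match = None
        for length in range(min(dictionary.max_len, n - i), 0, -1):
            surface = text[i : i + length]
            if surface in dictionary.entries:
                match = surface
                break
        if match is None:
            i += 1
            continue
        out.append(
            Entity(len(out), dictionary.entries[match], i, i + len(match), match)
        )
        i += len(match)
    return out
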