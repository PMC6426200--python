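"""Core domain types for mtDNA haplotype and population analysis.

Coordinates are 1-based inclusive throughout, following mtDNA convention:
variants are reported relative to a reference sequence (in real analyses the
rCRS) using the field's standard haplotype notation, e.g. ``16223T`` for a
substitution, ``309.1C`` (equivalently ``309iC``) for the first insertion
after position 309, ``16166d`` for a deletion, and ``@16189`` for a back
mutation to the ancestral state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Length of the canonical human mitochondrial reference sequence.
MT_LENGTH = 16569

#: Island population codes, plus the pooled eastern pair and a catch-all.
ISLAND_CODES = frozenset(
    {"HIE", "PAL", "GOM", "TFE", "GCA", "LAN", "FUE", "LAN&FUE", "other"}
)

#: Label used for the pooled Lanzarote + Fuerteventura sample.
POOLED_LAN_FUE = "LAN&FUE"


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    BACK_MUTATION = "back-mutation"


_SUB_RE = re.compile(r"^(\d+)([ACGTURYSWKMBDHVN])$", re.IGNORECASE)
_INS_RE = re.compile(r"^(\d+)\.(\d+)([ACGT]+)$", re.IGNORECASE)
_INS_I_RE = re.compile(r"^(\d+)i([ACGT]+)$", re.IGNORECASE)
_DEL_RE = re.compile(r"^(\d+)d(el)?$", re.IGNORECASE)
_BACK_RE = re.compile(r"^@(\d+)$")


@dataclass(frozen=True, order=True)
class Variant:
    """A single variant call relative to the reference.

    ``insert_index`` is the 1-based ordinal for multiple insertions at the
    same anchor position and 0 for every other kind.
    """

    position: int
    insert_index: int = 0
    kind: VariantKind = VariantKind.SUBSTITUTION
    state: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")
        if self.kind is VariantKind.INSERTION:
            if self.insert_index < 1:
                raise ValueError("insertions need insert_index >= 1")
            if not self.state:
                raise ValueError("insertions need an inserted state")
        else:
            if self.insert_index != 0:
                raise ValueError("insert_index must be 0 for non-insertions")
        if self.kind is VariantKind.SUBSTITUTION and len(self.state) != 1:
            raise ValueError(f"substitution state must be one base, got {self.state!r}")
        if self.kind in (VariantKind.DELETION, VariantKind.BACK_MUTATION) and self.state:
            raise ValueError(f"{self.kind.value} carries no state")

    @property
    def site(self) -> tuple[int, int]:
        """The (position, insert_index) locus this variant occupies."""
        return (self.position, self.insert_index)

    def __str__(self) -> str:
        if self.kind is VariantKind.SUBSTITUTION:
            return f"{self.position}{self.state}"
        if self.kind is VariantKind.INSERTION:
            return f"{self.position}.{self.insert_index}{self.state}"
        if self.kind is VariantKind.DELETION:
            return f"{self.position}d"
        return f"@{self.position}"

    @classmethod
    def parse(cls, token: str, max_position: int = MT_LENGTH) -> "Variant":
        """Parse one canonical variant token (a single variant only)."""
        variants = parse_variant_token(token, max_position=max_position)
        if len(variants) != 1:
            raise ValueError(f"token {token!r} encodes {len(variants)} variants")
        return variants[0]


def parse_variant_token(token: str, max_position: int = MT_LENGTH) -> list[Variant]:
    """Parse one text token into variants.

    Multi-base ``i`` insertions such as ``309iCC`` expand into consecutive
    insertion ordinals (``309.1C``, ``309.2C``).
    """
    token = token.strip()
    if not token:
        raise ValueError("empty variant token")

    def _check(pos: int) -> int:
        if not 1 <= pos <= max_position:
            raise ValueError(
                f"variant position {pos} outside reference (1..{max_position})"
            )
        return pos

    m = _BACK_RE.match(token)
    if m:
        return [Variant(_check(int(m.group(1))), kind=VariantKind.BACK_MUTATION)]
    m = _DEL_RE.match(token)
    if m:
        return [Variant(_check(int(m.group(1))), kind=VariantKind.DELETION)]
    m = _INS_RE.match(token)
    if m:
        pos, idx, states = _check(int(m.group(1))), int(m.group(2)), m.group(3).upper()
        return [
            Variant(pos, idx + i, VariantKind.INSERTION, s)
            for i, s in enumerate(states)
        ]
    m = _INS_I_RE.match(token)
    if m:
        pos, states = _check(int(m.group(1))), m.group(2).upper()
        return [
            Variant(pos, i + 1, VariantKind.INSERTION, s) for i, s in enumerate(states)
        ]
    m = _SUB_RE.match(token)
    if m:
        return [
            Variant(_check(int(m.group(1))), 0, VariantKind.SUBSTITUTION,
                    m.group(2).upper())
        ]
    raise ValueError(f"unparseable variant token {token!r}")


class Motif:
    """An ordered set of variants defining a haplotype.

    Variants are kept sorted by (position, insert_index); at most one variant
    per (position, insert_index, kind). Hashable and comparable, so motifs can
    key dictionaries and be ordered lexicographically by their text form.
    """

    __slots__ = ("_variants",)

    def __init__(self, variants: Iterable[Variant] = ()) -> None:
        seen: dict[tuple[int, int, VariantKind], Variant] = {}
        for v in variants:
            key = (v.position, v.insert_index, v.kind)
            if key in seen and seen[key] != v:
                raise ValueError(f"conflicting duplicate variant at {key}: {v}")
            seen[key] = v
        object.__setattr__(
            self,
            "_variants",
            tuple(sorted(seen.values(), key=lambda v: (v.position, v.insert_index, str(v)))),
        )

    @classmethod
    def parse(cls, text: str, max_position: int = MT_LENGTH) -> "Motif":
        """Parse a whitespace/comma-separated list of variant tokens."""
        tokens = [t for t in re.split(r"[\s,;]+", text.strip()) if t]
        out: list[Variant] = []
        for t in tokens:
            out.extend(parse_variant_token(t, max_position=max_position))
        return cls(out)

    @property
    def variants(self) -> tuple[Variant, ...]:
        return self._variants

    def site_states(self) -> dict[tuple[int, int], tuple[VariantKind, str]]:
        """Map each occupied (position, insert_index) to its (kind, state)."""
        return {v.site: (v.kind, v.state) for v in self._variants}

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._variants)

    def __len__(self) -> int:
        return len(self._variants)

    def __contains__(self, v: Variant) -> bool:
        return v in self._variants

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Motif) and self._variants == other._variants

    def __lt__(self, other: "Motif") -> bool:
        return str(self) < str(other)

    def __hash__(self) -> int:
        return hash(self._variants)

    def __str__(self) -> str:
        return " ".join(str(v) for v in self._variants)

    def __repr__(self) -> str:
        return f"Motif({str(self)!r})"

    def union(self, other: "Motif") -> "Motif":
        return Motif(self._variants + other.variants)

    def intersection(self, other: "Motif") -> "Motif":
        o = set(other.variants)
        return Motif(v for v in self._variants if v in o)

    def difference(self, other: "Motif") -> "Motif":
        o = set(other.variants)
        return Motif(v for v in self._variants if v not in o)

    def restrict(self, start: int, end: int) -> "Motif":
        """Variants whose position falls in [start, end] (1-based inclusive)."""
        return Motif(v for v in self._variants if start <= v.position <= end)


def compose_motifs(base: Motif, extra: Iterable[Variant]) -> Motif:
    """Apply variants on top of a base motif, as along a phylogeny path.

    A back mutation ``@p`` removes the variant at (p, 0) from the base; any
    other variant overwrites the state at its site.
    """
    sites: dict[tuple[int, int], Variant] = {v.site: v for v in base}
    for v in extra:
        if v.kind is VariantKind.BACK_MUTATION:
            sites.pop((v.position, 0), None)
        else:
            sites[v.site] = v
    return Motif(sites.values())


@dataclass(frozen=True)
class ReferenceSegment:
    """A reference subsequence with 1-based inclusive coordinates."""

    name: str
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} inconsistent with "
                f"coordinates {self.start}..{self.end}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise ValueError(f"position {position} outside segment "
                             f"{self.start}..{self.end}")
        return self.sequence[position - self.start]

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


#: Default HVRI analysis window.
HVRI_START, HVRI_END = 16000, 16400


@dataclass(frozen=True)
class RateConfig:
    """Molecular clock: expected years per substitution over the sequence.

    The default, one substitution every 3,624 years, is the whole-mitogenome
    rate corrected for purifying selection.
    """

    years_per_substitution: float = 3624.0

    def __post_init__(self) -> None:
        if not self.years_per_substitution > 0:
            raise ValueError("years_per_substitution must be > 0")


@dataclass
class SampleRecord:
    """One individual: provenance, haplotype motif and haplogroup call."""

    sample_id: str
    island: str
    period: str  # "ancient" | "modern"
    site: str = ""
    haplogroup: Optional[str] = None
    motif: Optional[Motif] = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.period not in ("ancient", "modern"):
            raise ValueError(f"period must be ancient|modern, got {self.period!r}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")

    @property
    def island_known(self) -> bool:
        return self.island in ISLAND_CODES


class FrequencyTable:
    """Haplogroup (or haplotype) counts per population.

    Internally a pandas DataFrame with populations as rows and categories as
    columns; ``n_g`` are the per-population totals (row sums).
    """

    def __init__(self, counts: pd.DataFrame) -> None:
        counts = counts.fillna(0).astype(int)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts

    @classmethod
    def from_dict(
        cls,
        data: Mapping[str, Mapping[str, int]],
        populations: Optional[Sequence[str]] = None,
        categories: Optional[Sequence[str]] = None,
    ) -> "FrequencyTable":
        """Build from {population: {category: count}} preserving given order."""
        df = pd.DataFrame.from_dict(data, orient="index").fillna(0)
        if populations is not None:
            df = df.reindex(index=list(populations), fill_value=0)
        if categories is not None:
            df = df.reindex(columns=list(categories), fill_value=0)
        return cls(df)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_g(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.n_g, axis=0)

    def population_counts(self, population: str) -> np.ndarray:
        return self.counts.loc[population].to_numpy()

    def pooled(self, labels: Sequence[str], new_label: str) -> "FrequencyTable":
        """Merge the given populations into one row labelled ``new_label``."""
        missing = [l for l in labels if l not in self.counts.index]
        if missing:
            raise KeyError(f"populations not in table: {missing}")
        merged = self.counts.loc[list(labels)].sum(axis=0)
        rest = self.counts.drop(index=list(labels))
        out_rows = {}
        inserted = False
        for pop in self.populations:
            if pop in labels:
                if not inserted:
                    out_rows[new_label] = merged
                    inserted = True
            else:
                out_rows[pop] = rest.loc[pop]
        return FrequencyTable(pd.DataFrame(out_rows).T[self.counts.columns])

    def subset(self, populations: Sequence[str]) -> "FrequencyTable":
        return FrequencyTable(self.counts.loc[list(populations)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FrequencyTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return (f"FrequencyTable({len(self.populations)} populations x "
                f"{len(self.categories)} categories, n={self.total})")


@dataclass(frozen=True)
class TreeNode:
    parent: Optional[str]
    variants: tuple[Variant, ...]


class PhyloTree:
    """A reduced haplogroup tree: label -> (parent, defining variants).

    The cumulative motif of a node is the composition of defining variants
    along the path from the root, with back mutations removing their
    ancestral variant.
    """

    def __init__(self, nodes: Mapping[str, TreeNode]) -> None:
        roots = [label for label, n in nodes.items() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        if nodes[self.root].variants:
            raise ValueError("root must carry an empty motif")
        self.nodes = dict(nodes)
        # validate reachability / acyclicity
        for label in self.nodes:
            seen = set()
            cur: Optional[str] = label
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through {cur!r}")
                seen.add(cur)
                if cur not in self.nodes:
                    raise ValueError(f"unknown parent {cur!r}")
                cur = self.nodes[cur].parent
            if self.root not in seen:
                raise ValueError(f"{label!r} not reachable from root")
        self._cumulative: dict[str, Motif] = {}

    def __contains__(self, label: str) -> bool:
        return label in self.nodes

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def parent(self, label: str) -> Optional[str]:
        return self.nodes[label].parent

    def depth(self, label: str) -> int:
        d = 0
        cur = self.nodes[label].parent
        while cur is not None:
            d += 1
            cur = self.nodes[cur].parent
        return d

    def path_from_root(self, label: str) -> list[str]:
        path = [label]
        cur = self.nodes[label].parent
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def cumulative_motif(self, label: str) -> Motif:
        if label not in self._cumulative:
            motif = Motif()
            for anc in self.path_from_root(label):
                motif = compose_motifs(motif, self.nodes[anc].variants)
            self._cumulative[label] = motif
        return self._cumulative[label]

    def descendants(self, label: str) -> list[str]:
        """All nodes in the clade rooted at ``label`` (inclusive)."""
        out = []
        for other in self.nodes:
            cur: Optional[str] = other
            while cur is not None:
                if cur == label:
                    out.append(other)
                    break
                cur = self.nodes[cur].parent
        return out
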