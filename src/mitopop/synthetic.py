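"""Synthetic data with the statistical structure the analysis assumes.

Island populations are multinomial draws from fixed haplogroup frequency
vectors; sequences are near-identical HVRI fragments derived from haplogroup
motifs plus Poisson-distributed rare private substitutions; admixed
populations are multinomial draws from a known linear combination of
parental frequency vectors; genealogies are rooted star or random
bifurcating trees on which each lineage accumulates Poisson mutations at a
known clock rate. Every generator is seed-deterministic and returns truth
labels alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .haplotyping import DEFAULT_EXCLUSIONS, ExclusionRules, motif_to_sequence
from .io import read_phylotree
from .model import (
    HVRI_END,
    HVRI_START,
    FrequencyTable,
    Motif,
    PhyloTree,
    RateConfig,
    ReferenceSegment,
    SampleRecord,
    Variant,
    VariantKind,
    compose_motifs,
)

_BASES = "ACGT"

# Haplogroup absolute counts for the six ancient island populations
# (categories x populations), the study system all defaults emulate.
_TABLE1_POPULATIONS = ("HIE", "PAL", "TFE", "GOM", "GCA", "LAN&FUE")
_TABLE1_COUNTS: dict[str, tuple[int, ...]] = {
    "H": (12, 10, 15, 2, 33, 13),
    "H1cf": (57, 8, 6, 2, 1, 0),
    "H4a1e": (0, 0, 0, 0, 3, 1),
    "HV0": (0, 0, 1, 0, 0, 0),
    "J": (0, 3, 4, 5, 2, 0),
    "K": (0, 1, 1, 1, 2, 0),
    "L1/L2": (0, 2, 2, 1, 1, 0),
    "L3": (0, 0, 2, 4, 1, 0),
    "L3b1a12": (0, 0, 0, 0, 5, 0),
    "M1": (0, 0, 0, 0, 1, 0),
    "Other T": (0, 1, 0, 0, 3, 0),
    "T2c1": (0, 3, 12, 0, 15, 2),
    "U5": (0, 0, 0, 0, 3, 1),
    "U6a": (0, 0, 2, 0, 6, 2),
    "U6b": (0, 2, 8, 38, 4, 0),
    "U6c": (0, 0, 0, 0, 5, 1),
    "U7": (1, 0, 0, 0, 0, 0),
    "W1e1": (0, 1, 0, 0, 0, 0),
    "X3a": (0, 4, 0, 4, 2, 0),
}

#: Representative haplogroup node (in the bundled tree) for each category.
DEFAULT_MOTIF_CATALOG_NODES: dict[str, str] = {
    "H": "H",
    "H1cf": "H1cf",
    "H4a1e": "H4a1e",
    "HV0": "HV0",
    "J": "J",
    "K": "K",
    "L1/L2": "L1b",
    "L3": "L3",
    "L3b1a12": "L3b1a12",
    "M1": "M1",
    "Other T": "T",
    "T2c1": "T2c1",
    "U5": "U5",
    "U6a": "U6a",
    "U6b": "U6b1a",
    "U6c": "U6c",
    "U7": "U7",
    "W1e1": "W1e1",
    "X3a": "X3a",
}


def make_table1_fixture() -> FrequencyTable:
    """The bundled haplogroup count table for the six ancient populations."""
    import pandas as pd

    df = pd.DataFrame(_TABLE1_COUNTS, index=list(_TABLE1_POPULATIONS))
    return FrequencyTable(df)


def default_phylotree() -> PhyloTree:
    """Load the bundled reduced haplogroup tree."""
    with resources.as_file(
        resources.files("mitopop.data") / "phylotree_hvri.json"
    ) as path:
        return read_phylotree(path)


def synthetic_hvri_reference(seed: int = 160000) -> ReferenceSegment:
    """A deterministic synthetic HVRI reference segment (16000..16400).

    A stand-in for the corresponding rCRS window: random bases, adjusted so
    that every substitution in the bundled tree is a real change (the
    reference base never equals a tree variant's derived state).
    """
    rng = np.random.default_rng(seed)
    length = HVRI_END - HVRI_START + 1
    seq = list(rng.choice(list(_BASES), size=length))
    tree = default_phylotree()
    for label in tree:
        for v in tree.nodes[label].variants:
            if v.kind is VariantKind.SUBSTITUTION and HVRI_START <= v.position <= HVRI_END:
                i = v.position - HVRI_START
                if seq[i] == v.state:
                    seq[i] = _BASES[(_BASES.index(v.state) + 1) % 4]
    return ReferenceSegment("synthetic-HVRI:16000-16400", "".join(seq),
                            HVRI_START, HVRI_END)


def default_motif_catalog(
    tree: Optional[PhyloTree] = None,
    segment: Optional[ReferenceSegment] = None,
) -> dict[str, Motif]:
    """Category -> cumulative HVRI motif of its representative haplogroup."""
    tree = tree or default_phylotree()
    catalog = {}
    for category, node in DEFAULT_MOTIF_CATALOG_NODES.items():
        motif = tree.cumulative_motif(node)
        if segment is not None:
            motif = motif.restrict(segment.start, segment.end)
        catalog[category] = motif
    return catalog


@dataclass
class ArchipelagoSpec:
    """Study design for a synthetic archipelago.

    ``islands`` holds (label, n, frequency vector over ``categories``);
    ``private_mutation_rate`` is the Poisson mean of rare private
    substitutions added per sampled sequence.
    """

    islands: list[tuple[str, int, np.ndarray]]
    categories: list[str]
    motif_catalog: dict[str, Motif]
    private_mutation_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.private_mutation_rate < 0:
            raise ValueError("private_mutation_rate must be >= 0")
        for label, n, freqs in self.islands:
            freqs = np.asarray(freqs, dtype=float)
            if n < 0:
                raise ValueError(f"island {label!r}: n must be >= 0")
            if len(freqs) != len(self.categories):
                raise ValueError(f"island {label!r}: frequency vector length")
            if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError(f"island {label!r}: frequencies must sum to 1")


def canaries_spec(
    private_mutation_rate: float = 0.5,
    seed: int = 0,
    tree: Optional[PhyloTree] = None,
    segment: Optional[ReferenceSegment] = None,
) -> ArchipelagoSpec:
    """Default archipelago mirroring the six ancient island populations."""
    table = make_table1_fixture()
    catalog = default_motif_catalog(tree, segment)
    islands = [
        (pop, int(table.n_g[pop]), table.frequencies().loc[pop].to_numpy())
        for pop in table.populations
    ]
    return ArchipelagoSpec(
        islands=islands,
        categories=table.categories,
        motif_catalog=catalog,
        private_mutation_rate=private_mutation_rate,
        seed=seed,
    )


def sample_population(
    freqs: Sequence[float], n: int, seed: Optional[int] = None
) -> np.ndarray:
    """One multinomial draw of category counts."""
    freqs = np.asarray(freqs, dtype=float)
    if (freqs < 0).any():
        raise ValueError("frequencies must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(n, freqs / freqs.sum())


def _random_private_substitutions(
    rng: np.random.Generator,
    k: int,
    base_motif: Motif,
    segment: ReferenceSegment,
    exclusions: ExclusionRules,
) -> list[Variant]:
    occupied = {v.position for v in base_motif}
    allowed = [
        p
        for p in range(segment.start, segment.end + 1)
        if p not in occupied and p not in exclusions.substitution_positions
    ]
    positions = rng.choice(allowed, size=min(k, len(allowed)), replace=False)
    out = []
    for pos in sorted(int(p) for p in positions):
        ref_base = segment.base_at(pos)
        state = _BASES[(_BASES.index(ref_base) + rng.integers(1, 4)) % 4]
        out.append(Variant(pos, 0, VariantKind.SUBSTITUTION, state))
    return out


def generate_sequences(
    spec: ArchipelagoSpec,
    segment: Optional[ReferenceSegment] = None,
    exclusions: ExclusionRules = DEFAULT_EXCLUSIONS,
) -> tuple[list[tuple[str, str]], list[SampleRecord]]:
    """FASTA records plus a truth sample table for a synthetic archipelago.

    Each sample's sequence realizes its haplogroup motif plus
    Poisson(private_mutation_rate) private substitutions at non-excluded
    positions, so exclusion-aware round trips are exact. Truth haplogroup
    labels (the representative tree node per category) are retained.
    """
    segment = segment or synthetic_hvri_reference()
    rng = np.random.default_rng(spec.seed)
    fasta: list[tuple[str, str]] = []
    samples: list[SampleRecord] = []
    for label, n, freqs in spec.islands:
        if n == 0:
            continue
        counts = rng.multinomial(n, np.asarray(freqs, dtype=float))
        idx = 0
        for category, count in zip(spec.categories, counts):
            base = spec.motif_catalog[category]
            for _ in range(count):
                idx += 1
                k = int(rng.poisson(spec.private_mutation_rate))
                privates = _random_private_substitutions(
                    rng, k, base, segment, exclusions
                )
                motif = compose_motifs(base, privates)
                sid = f"{label}.{idx:04d}"
                fasta.append((sid, motif_to_sequence(motif, segment)))
                truth_node = DEFAULT_MOTIF_CATALOG_NODES.get(category, category)
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        island=label,
                        period="ancient",
                        site=f"{label}_s{idx:04d}",
                        haplogroup=truth_node,
                        motif=motif,
                    )
                )
    return fasta, samples


def generate_admixed(
    parentals: Sequence[Sequence[float]],
    m: Sequence[float],
    n: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Multinomial counts from the mixture sum_k m_k * parental_k."""
    m = np.asarray(m, dtype=float)
    P = np.column_stack([np.asarray(p, dtype=float) for p in parentals])
    if (m < 0).any() or abs(m.sum() - 1.0) > 1e-9:
        raise ValueError("mixing proportions must be non-negative and sum to 1")
    if P.shape[1] != len(m):
        raise ValueError("number of parentals does not match proportions")
    mixture = P @ m
    return sample_population(mixture, n, seed)


def simulate_genealogy(
    root: Motif,
    n_lineages: int,
    age_years: float,
    rate: RateConfig = RateConfig(),
    topology: str = "star",
    seed: Optional[int] = None,
    segment: Optional[ReferenceSegment] = None,
    exclusions: ExclusionRules = DEFAULT_EXCLUSIONS,
) -> list[tuple[Motif, int]]:
    """Simulate sampled haplotypes descending from a root at a known age.

    star: each lineage independently accumulates
    Poisson(age_years / years_per_substitution) substitutions at random
    non-excluded positions. yule: a random bifurcating tree whose root-leaf
    branch lengths all sum to ``age_years``, with Poisson mutations per
    branch. Identical motifs are aggregated with multiplicities.
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    if n_lineages < 1:
        raise ValueError("need at least one lineage")
    segment = segment or synthetic_hvri_reference()
    rng = np.random.default_rng(seed)
    mean = age_years / rate.years_per_substitution

    leaves: list[Motif] = []
    if topology == "star":
        for _ in range(n_lineages):
            k = int(rng.poisson(mean))
            privates = _random_private_substitutions(rng, k, root, segment, exclusions)
            leaves.append(compose_motifs(root, privates))
    elif topology == "yule":
        def grow(count: int, t0: float, motif: Motif) -> None:
            if count == 1:
                k = int(rng.poisson((age_years - t0) / rate.years_per_substitution))
                privates = _random_private_substitutions(
                    rng, k, motif, segment, exclusions
                )
                leaves.append(compose_motifs(motif, privates))
                return
            t_split = float(rng.uniform(t0, age_years))
            k = int(rng.poisson((t_split - t0) / rate.years_per_substitution))
            privates = _random_private_substitutions(rng, k, motif, segment, exclusions)
            branch_motif = compose_motifs(motif, privates)
            left = int(rng.integers(1, count))
            grow(left, t_split, branch_motif)
            grow(count - left, t_split, branch_motif)

        grow(n_lineages, 0.0, root)
    else:
        raise ValueError(f"unknown topology {topology!r}")

    mult: dict[Motif, int] = {}
    for m in leaves:
        mult[m] = mult.get(m, 0) + 1
    return sorted(mult.items(), key=lambda kv: str(kv[0]))
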