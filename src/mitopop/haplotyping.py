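"""Sequence-to-motif conversion and haplogroup assignment.

A query sequence (typically an assembled HVRI fragment) is globally aligned
to the reference segment with free end gaps, differences are called as
variants in canonical notation, hypervariable indel/hotspot positions are
set aside, and the resulting motif is scored against a reduced haplogroup
tree with an unweighted Kulczynski similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .model import (
    Motif,
    PhyloTree,
    ReferenceSegment,
    SampleRecord,
    Variant,
    VariantKind,
)

# Fixed alignment scoring; sequences are near-identical so the exact values
# are uncritical, but they are pinned for determinism.
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1.0, -1.0, -2.0, -1.0


@dataclass(frozen=True)
class ExclusionRules:
    """Positions excluded from phylogenetic analysis.

    Indels around the classic unstable homopolymer positions and
    substitutions at mutational hotspots are recorded separately and kept
    out of motifs used for haplogrouping, networks and dating. Indels are
    matched within ``indel_radius`` of the listed anchors because aligners
    may place a homopolymer-run indel at any position of the run.
    """

    indel_positions: frozenset[int] = frozenset({309, 522, 573, 16193})
    substitution_positions: frozenset[int] = frozenset({16519})
    indel_radius: int = 5

    def excludes(self, v: Variant) -> bool:
        if v.kind in (VariantKind.INSERTION, VariantKind.DELETION):
            return any(
                abs(v.position - p) <= self.indel_radius
                for p in self.indel_positions
            )
        if v.kind is VariantKind.SUBSTITUTION:
            return v.position in self.substitution_positions
        return False

    def split(self, variants: Iterable[Variant]) -> tuple[Motif, Motif]:
        """Partition variants into (kept, excluded) motifs."""
        kept, excluded = [], []
        for v in variants:
            (excluded if self.excludes(v) else kept).append(v)
        return Motif(kept), Motif(excluded)


DEFAULT_EXCLUSIONS = ExclusionRules()


@dataclass(frozen=True)
class Alignment:
    """A gapped pairwise alignment of query against the reference segment."""

    ref_aligned: str
    query_aligned: str
    identity: float
    reverse_complemented: bool
    ref_start: int  # 1-based reference coordinate of first aligned ref base


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _MATCH
    aligner.mismatch_score = _MISMATCH
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    # free end gaps: partial fragments are expected
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _identity(ref_gapped: str, qry_gapped: str) -> float:
    matches = cols = 0
    for r, q in zip(ref_gapped, qry_gapped):
        if r != "-" and q != "-":
            cols += 1
            if r == q:
                matches += 1
    return matches / cols if cols else 0.0


def align_to_reference(
    seq: str,
    ref: ReferenceSegment,
    min_identity: float = 0.80,
    try_reverse_complement: bool = True,
) -> Alignment:
    """Globally align a sequence to the reference segment (free end gaps).

    The orientation with the higher aligned identity is kept; alignments
    below ``min_identity`` are rejected as non-homologous.
    """
    seq = seq.upper().replace("U", "T")
    if not 0.5 * len(ref) <= len(seq) <= 2.0 * len(ref):
        raise ValueError(
            f"sequence length {len(seq)} outside [0.5x, 2x] of reference "
            f"length {len(ref)}"
        )
    aligner = _make_aligner()

    def _best(query: str) -> tuple[str, str, float]:
        aln = aligner.align(ref.sequence, query)[0]
        r, q = str(aln[0]), str(aln[1])
        return r, q, _identity(r, q)

    r_fwd, q_fwd, id_fwd = _best(seq)
    chosen = (r_fwd, q_fwd, id_fwd, False)
    if try_reverse_complement:
        r_rev, q_rev, id_rev = _best(reverse_complement(seq))
        if id_rev > id_fwd:
            chosen = (r_rev, q_rev, id_rev, True)
    r, q, ident, revd = chosen
    if ident < min_identity:
        raise ValueError(
            f"alignment identity {ident:.2f} below {min_identity:.2f}: "
            "sequence not homologous to the reference segment"
        )
    return Alignment(r, q, ident, revd, ref.start)


def call_variants(
    alignment: Alignment,
    exclusions: ExclusionRules = DEFAULT_EXCLUSIONS,
) -> tuple[Motif, Motif]:
    """Call variants from an alignment; returns (motif, excluded).

    End-gap regions of the query (missing fragment coverage) yield no calls.
    Insertions are anchored to the preceding reference position with 1-based
    insertion ordinals. Excluded calls are reported, not silently dropped.
    """
    r, q = alignment.ref_aligned, alignment.query_aligned
    # clip query end gaps (and ref end gaps = query overhang)
    lead = 0
    while lead < len(q) and (q[lead] == "-" or r[lead] == "-"):
        lead += 1
    trail = len(q)
    while trail > lead and (q[trail - 1] == "-" or r[trail - 1] == "-"):
        trail -= 1
    # count reference bases consumed before the clipped region
    ref_pos = alignment.ref_start + sum(1 for c in r[:lead] if c != "-") - 1

    calls: list[Variant] = []
    insert_index = 0
    for rc, qc in zip(r[lead:trail], q[lead:trail]):
        if rc != "-":
            ref_pos += 1
            insert_index = 0
            if qc == "-":
                calls.append(Variant(ref_pos, kind=VariantKind.DELETION))
            elif qc != rc:
                calls.append(Variant(ref_pos, 0, VariantKind.SUBSTITUTION, qc))
        else:
            insert_index += 1
            calls.append(Variant(ref_pos, insert_index, VariantKind.INSERTION, qc))
    return exclusions.split(calls)


def motif_to_sequence(motif: Motif, ref: ReferenceSegment) -> str:
    """Realize a motif as a concrete sequence over the reference segment.

    Inverse of ``call_variants`` (up to the exclusion set) for motifs whose
    positions all fall inside the segment.
    """
    by_pos: dict[int, list[Variant]] = {}
    for v in motif:
        if not ref.contains(v.position):
            raise ValueError(
                f"variant {v} outside segment {ref.start}..{ref.end}"
            )
        by_pos.setdefault(v.position, []).append(v)
    out: list[str] = []
    for offset, base in enumerate(ref.sequence):
        pos = ref.start + offset
        emitted = base
        inserts: list[Variant] = []
        for v in by_pos.get(pos, ()):
            if v.kind is VariantKind.SUBSTITUTION:
                emitted = v.state
            elif v.kind is VariantKind.DELETION:
                emitted = ""
            elif v.kind is VariantKind.INSERTION:
                inserts.append(v)
            # back mutations revert to the reference state: no-op here
        out.append(emitted)
        for v in sorted(inserts, key=lambda v: v.insert_index):
            out.append(v.state)
    return "".join(out)


@dataclass
class AssignmentResult:
    """Best haplogroup for a motif, with score and ranked alternatives."""

    haplogroup: str
    score: float
    expected_found: int
    expected_total: int
    private_variants: Motif
    ranked_alternatives: list[tuple[str, float]] = field(default_factory=list)


def _kulczynski(motif_set: set[Variant], expected: set[Variant]) -> float:
    inter = len(motif_set & expected)
    term_e = inter / len(expected) if expected else 1.0
    term_m = inter / len(motif_set) if motif_set else 1.0
    return 0.5 * (term_e + term_m)


def assign_haplogroup(
    motif: Motif,
    tree: PhyloTree,
    segment: Optional[ReferenceSegment] = None,
) -> AssignmentResult:
    """Score a motif against every haplogroup in the reduced tree.

    score(h) = 1/2 (|M n E_h| / |E_h| + |M n E_h| / |M|), the Kulczynski
    similarity between the observed motif M and the haplogroup's cumulative
    defining variants E_h restricted to the analyzed segment. Ties break
    toward the deeper node, then lexicographically.
    """
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    motif_set = set(motif)
    scored: list[tuple[str, float, set[Variant]]] = []
    for label in tree:
        expected = tree.cumulative_motif(label)
        if segment is not None:
            expected = expected.restrict(segment.start, segment.end)
        scored.append((label, _kulczynski(motif_set, set(expected)), set(expected)))
    scored.sort(key=lambda t: (-t[1], -tree.depth(t[0]), t[0]))
    best_label, best_score, best_expected = scored[0]
    return AssignmentResult(
        haplogroup=best_label,
        score=best_score,
        expected_found=len(motif_set & best_expected),
        expected_total=len(best_expected),
        private_variants=Motif(motif_set - best_expected),
        ranked_alternatives=[(l, s) for l, s, _ in scored[1:]],
    )


def dedup_by_site(
    samples: Sequence[SampleRecord],
    scope: str = "population-analysis",
) -> list[SampleRecord]:
    """Drop potentially related ancient samples from the same site.

    Samples recovered from one burial site may be maternal relatives, so for
    population analysis only one ancient record per (site, haplogroup) is
    retained; for coalescence dating only one per site. The record with the
    smallest sample_id survives; modern records pass through untouched.
    """
    if scope not in ("population-analysis", "dating"):
        raise ValueError(f"unknown dedup scope {scope!r}")
    best: dict[tuple, SampleRecord] = {}
    order: list[tuple] = []
    for s in samples:
        if s.period != "ancient":
            key = ("modern", s.sample_id)
        elif scope == "population-analysis":
            key = ("ancient", s.site, s.haplogroup)
        else:
            key = ("ancient", s.site)
        if key not in best:
            best[key] = s
            order.append(key)
        elif s.sample_id < best[key].sample_id:
            best[key] = s
    return [best[key] for key in order]
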