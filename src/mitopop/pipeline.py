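"""End-to-end pipeline: haplotype -> assign -> dedup -> statistics.

Driven by a single YAML config; every stage writes TSV/JSON outputs under
the output directory and the run is summarized in a JSON manifest recording
config, seed and produced files, so identical config + seed reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .admixture import bootstrap_admixture
from .distance import distance_matrix, smacof_mds
from .haplotyping import (
    DEFAULT_EXCLUSIONS,
    align_to_reference,
    assign_haplogroup,
    call_variants,
    dedup_by_site,
)
from .io import (
    read_fasta,
    read_frequency_table,
    read_phylotree,
    read_reference,
    read_sample_table,
    write_distance_matrix,
    write_frequency_table,
    write_manifest,
    write_network,
    write_sample_table,
)
from .model import POOLED_LAN_FUE, FrequencyTable, RateConfig, SampleRecord
from .network import date_clade
from .popstats import asymmetry_scan, haplogroup_frequencies, nei_diversity

logger = logging.getLogger("mitopop")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name and offending input."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    fasta: Optional[Path] = None
    reference: Optional[Path] = None
    reference_start: int = 1
    samples: Optional[Path] = None
    frequencies: Optional[Path] = None
    phylotree: Optional[Path] = None
    categories: Optional[list[str]] = None
    pool_lan_fue: bool = True
    partition: Optional[dict[str, str]] = None
    fisher_exclude: list[str] = field(default_factory=list)
    clock_rate: float = 3624.0
    epsilon: int = 0
    bootstrap: int = 1000
    admixture: Optional[dict] = None  # {"hybrid": pop, "parentals": [pop, ...]}
    date_clades: list[str] = field(default_factory=list)
    stages: list[str] = field(
        default_factory=lambda: [
            "haplotype", "frequencies", "diversity", "fisher", "fst", "mds",
            "admixture", "dating",
        ]
    )

    @classmethod
    def from_dict(cls, doc: dict, base: Optional[Path] = None) -> "RunConfig":
        base = base or Path(".")

        def _p(key: str) -> Optional[Path]:
            return (base / doc[key]).resolve() if doc.get(key) else None

        cfg = cls(
            out_dir=Path(doc.get("out_dir", "mitopop_run")),
            seed=int(doc.get("seed", 0)),
            fasta=_p("fasta"),
            reference=_p("reference"),
            reference_start=int(doc.get("reference_start", 1)),
            samples=_p("samples"),
            frequencies=_p("frequencies"),
            phylotree=_p("phylotree"),
            categories=doc.get("categories"),
            pool_lan_fue=bool(doc.get("pool_lan_fue", True)),
            partition=doc.get("partition"),
            fisher_exclude=list(doc.get("fisher_exclude", [])),
            clock_rate=float(doc.get("clock_rate", 3624.0)),
            epsilon=int(doc.get("epsilon", 0)),
            bootstrap=int(doc.get("bootstrap", 1000)),
            admixture=doc.get("admixture"),
            date_clades=list(doc.get("date_clades", [])),
            stages=list(doc.get("stages", [
                "haplotype", "frequencies", "diversity", "fisher",
                "fst", "mds", "admixture", "dating",
            ])),
        )
        for key in ("fasta", "reference", "samples", "frequencies", "phylotree"):
            path = getattr(cfg, key)
            if path is not None and not Path(path).exists():
                raise PipelineError(f"startup: input file does not exist: {path}")
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) for k, v in vars(config).items()},
        "outputs": {},
    }
    samples: list[SampleRecord] = []
    freqs: Optional[FrequencyTable] = None
    tree = None
    segment = None

    def _stage(name: str) -> bool:
        return name in config.stages

    try:
        if config.phylotree is not None:
            tree = read_phylotree(config.phylotree)
        if config.reference is not None:
            segment = read_reference(config.reference, start=config.reference_start)
    except Exception as exc:
        raise PipelineError(f"startup: {exc}") from exc

    if _stage("haplotype") and config.fasta is not None:
        try:
            if segment is None:
                raise ValueError("haplotyping requires a reference")
            records = read_fasta(config.fasta)
            provenance = {
                s.sample_id: s for s in (
                    read_sample_table(config.samples) if config.samples else []
                )
            }
            for sid, seq in records:
                aln = align_to_reference(seq, segment)
                motif, _excluded = call_variants(aln)
                meta = provenance.get(sid)
                rec = SampleRecord(
                    sample_id=sid,
                    island=meta.island if meta else "other",
                    period=meta.period if meta else "ancient",
                    site=meta.site if meta else sid,
                    motif=motif,
                )
                if tree is not None:
                    rec.haplogroup = assign_haplogroup(
                        motif, tree, segment=segment
                    ).haplogroup
                samples.append(rec)
            samples = dedup_by_site(samples, scope="population-analysis")
            write_sample_table(samples, out / "assigned.tsv")
            manifest["outputs"]["assigned"] = str(out / "assigned.tsv")
        except Exception as exc:
            raise PipelineError(f"haplotype: {exc}") from exc
    elif config.samples is not None:
        samples = read_sample_table(config.samples)
        samples = dedup_by_site(samples, scope="population-analysis")

    if _stage("frequencies"):
        try:
            if config.frequencies is not None:
                freqs = read_frequency_table(config.frequencies)
            elif samples:
                freqs = haplogroup_frequencies(
                    samples,
                    categories=config.categories,
                    pool_lan_fue=config.pool_lan_fue,
                )
            if freqs is not None:
                write_frequency_table(freqs, out / "frequencies.tsv")
                manifest["outputs"]["frequencies"] = str(out / "frequencies.tsv")
        except Exception as exc:
            raise PipelineError(f"frequencies: {exc}") from exc

    if _stage("diversity") and freqs is not None:
        try:
            rows = []
            for pop in freqs.populations:
                counts = freqs.population_counts(pop)
                if counts.sum() < 2:
                    logger.warning("diversity: %s has n < 2; skipped", pop)
                    continue
                d = nei_diversity(counts)
                rows.append({
                    "population": pop, "n": d.n, "k": d.k,
                    "H_percent": round(100 * d.H, 4),
                    "SE_percent": round(100 * d.SE, 4),
                })
            pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
            manifest["outputs"]["diversity"] = str(out / "diversity.tsv")
        except Exception as exc:
            raise PipelineError(f"diversity: {exc}") from exc

    if _stage("fisher") and freqs is not None:
        try:
            scan = asymmetry_scan(
                freqs,
                partition=config.partition,
                exclude=config.fisher_exclude,
            )
            scan.to_csv(out / "fisher_scan.tsv", sep="\t", index=False)
            manifest["outputs"]["fisher_scan"] = str(out / "fisher_scan.tsv")
        except Exception as exc:
            raise PipelineError(f"fisher: {exc}") from exc

    dm = None
    if _stage("fst") and freqs is not None and len(freqs.populations) >= 2:
        try:
            dm = distance_matrix(freqs)
            write_distance_matrix(dm, out / "distances.tsv")
            manifest["outputs"]["distances"] = str(out / "distances.tsv")
        except Exception as exc:
            raise PipelineError(f"fst: {exc}") from exc

    if _stage("mds") and dm is not None and len(dm) > 2:
        try:
            mds = smacof_mds(dm, dims=2, seed=config.seed)
            coords = pd.DataFrame(
                mds.coordinates, index=mds.labels, columns=["dim1", "dim2"]
            )
            coords["stress"] = mds.stress
            coords.to_csv(out / "mds.tsv", sep="\t", index_label="population")
            manifest["outputs"]["mds"] = str(out / "mds.tsv")
        except Exception as exc:
            raise PipelineError(f"mds: {exc}") from exc

    if _stage("admixture") and config.admixture and freqs is not None:
        try:
            hybrid = freqs.population_counts(config.admixture["hybrid"])
            parentals = [
                freqs.population_counts(p) for p in config.admixture["parentals"]
            ]
            res = bootstrap_admixture(
                hybrid, parentals, B=config.bootstrap, seed=config.seed
            )
            pd.DataFrame({
                "parental": list(config.admixture["parentals"]),
                "proportion": np.round(res.m, 4),
                "SE": np.round(res.SE, 4),
            }).to_csv(out / "admixture.tsv", sep="\t", index=False)
            manifest["outputs"]["admixture"] = str(out / "admixture.tsv")
        except Exception as exc:
            raise PipelineError(f"admixture: {exc}") from exc

    if _stage("dating") and config.date_clades and tree is not None and samples:
        try:
            rows = []
            for clade in config.date_clades:
                r = date_clade(
                    samples, clade, tree,
                    rate=RateConfig(config.clock_rate),
                    segment=segment,
                    epsilon=config.epsilon,
                )
                rows.append({
                    "clade": clade, "n": r.n, "rho": round(r.rho, 4),
                    "sigma": round(r.sigma, 4),
                    "age_years": round(r.age_years, 1),
                    "age_se_years": round(r.age_se_years, 1),
                    "low_information": r.low_information,
                })
            pd.DataFrame(rows).to_csv(out / "dating.tsv", sep="\t", index=False)
            manifest["outputs"]["dating"] = str(out / "dating.tsv")
        except Exception as exc:
            raise PipelineError(f"dating: {exc}") from exc

    write_manifest(manifest, out / "manifest.json")
    return manifest
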