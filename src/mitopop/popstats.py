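"""Frequency tables, Nei gene diversity and exact Fisher asymmetry tests.

Diversity uses Nei's unbiased estimator H = n/(n-1) (1 - sum p_i^2) with his
sampling variance; geographic asymmetry of haplogroup distributions is
tested category by category with a fully enumerated two-tailed Fisher exact
test on 2x2 present/absent x east/west tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import POOLED_LAN_FUE, FrequencyTable, SampleRecord

#: Default east/west split of the archipelago: islands nearer the continent
#: against the western group.
DEFAULT_PARTITION: dict[str, str] = {
    "GCA": "east",
    POOLED_LAN_FUE: "east",
    "LAN": "east",
    "FUE": "east",
    "HIE": "west",
    "PAL": "west",
    "TFE": "west",
    "GOM": "west",
}


def categorize(haplogroup: str, categories: Sequence[str]) -> Optional[str]:
    """Map a haplogroup label onto a mixed-granularity category schema.

    The schema may mix generic and specific labels (e.g. "H" next to "H1cf"):
    a haplogroup counts toward the most specific (longest-prefix) matching
    category. Slash buckets ("L1/L2") match either prefix; "Other X" buckets
    absorb X-prefixed labels not captured by a more specific category.
    """
    best: Optional[str] = None
    best_key: tuple[int, int] = (-1, -1)
    for cat in categories:
        for option in cat.split("/"):
            is_other = option.startswith("Other ")
            prefix = option[6:] if is_other else option
            if haplogroup == prefix or haplogroup.startswith(prefix):
                key = (len(prefix), 0 if is_other else 1)
                if key > best_key:
                    best, best_key = cat, key
    return best


def haplogroup_frequencies(
    samples: Sequence[SampleRecord],
    by: str = "island",
    categories: Optional[Sequence[str]] = None,
    pool_lan_fue: bool = False,
    level: str = "haplogroup",
    strict: bool = False,
) -> FrequencyTable:
    """Tabulate per-population counts from sample records.

    ``by`` selects the population key attribute ("island" or "site");
    ``level`` counts haplogroups or full haplotype motifs. With a category
    schema, haplogroups are folded onto it via :func:`categorize`.
    """
    counts: dict[str, dict[str, int]] = {}
    pops: list[str] = []
    cats: list[str] = [] if categories is None else list(categories)
    for s in samples:
        if level == "haplogroup":
            label = s.haplogroup
        elif level == "haplotype":
            label = str(s.motif) if s.motif is not None else None
        else:
            raise ValueError(f"unknown level {level!r}")
        if label is None:
            if strict:
                raise ValueError(f"sample {s.sample_id!r} has no {level}")
            continue
        if categories is not None and level == "haplogroup":
            cat = categorize(label, categories)
            if cat is None:
                if strict:
                    raise ValueError(
                        f"sample {s.sample_id!r}: haplogroup {label!r} matches "
                        "no category"
                    )
                continue
            label = cat
        pop = getattr(s, by)
        if pool_lan_fue and pop in ("LAN", "FUE"):
            pop = POOLED_LAN_FUE
        if pop not in counts:
            counts[pop] = {}
            pops.append(pop)
        counts[pop][label] = counts[pop].get(label, 0) + s.multiplicity
        if categories is None and label not in cats:
            cats.append(label)
    if not counts:
        return FrequencyTable(pd.DataFrame(dtype=int))
    return FrequencyTable.from_dict(counts, populations=pops, categories=cats)


@dataclass(frozen=True)
class DiversityResult:
    """Nei gene diversity with its sampling standard error."""

    H: float
    SE: float
    n: int
    k: int

    def as_percent(self) -> tuple[float, float]:
        return 100.0 * self.H, 100.0 * self.SE


def nei_diversity(counts: Sequence[int]) -> DiversityResult:
    """Nei's unbiased gene diversity and standard error.

    H = n/(n-1) (1 - sum p_i^2);
    V(H) = 2/(n(n-1)) { 2(n-2)(sum p_i^3 - (sum p_i^2)^2)
                        + sum p_i^2 - (sum p_i^2)^2 };  SE = sqrt(V).
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if (np.asarray(counts) < 0).any():
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {int(n)}")
    p = c / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    H = n / (n - 1.0) * (1.0 - s2)
    V = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    SE = float(np.sqrt(max(V, 0.0)))
    return DiversityResult(H=float(H), SE=SE, n=int(n), k=len(c))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts: rows = category present/absent, columns = east/west."""

    a: int  # present, east
    b: int  # present, west
    c: int  # absent, east
    d: int  # absent, west

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


#: Relative tolerance for floating-point ties among hypergeometric terms.
_TIE_RTOL = 1e-7


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p by full enumeration of the support.

    p = sum of hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table (with a 1e-7
    relative tolerance for floating ties). Terms use log-gamma, so margins in
    the hundreds are exact to double precision. A zero margin gives p = 1.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = np.asarray(table, dtype=int)
    n_present = a + b
    n_east = a + c
    N = a + b + c + d
    if n_present == 0 or n_east == 0 or n_present == N or n_east == N:
        return 1.0

    def log_pmf(k: np.ndarray) -> np.ndarray:
        # P(X = k), X ~ Hypergeometric(N, n_east, n_present)
        return (
            gammaln(n_present + 1)
            - gammaln(k + 1)
            - gammaln(n_present - k + 1)
            + gammaln(N - n_present + 1)
            - gammaln(n_east - k + 1)
            - gammaln(N - n_present - n_east + k + 1)
            - gammaln(N + 1)
            + gammaln(n_east + 1)
            + gammaln(N - n_east + 1)
        )

    lo = max(0, n_present + n_east - N)
    hi = min(n_present, n_east)
    support = np.arange(lo, hi + 1)
    logp = log_pmf(support)
    log_obs = float(log_pmf(np.array([a]))[0])
    keep = logp <= log_obs + np.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(logp[keep]).sum()))


def asymmetry_scan(
    freqs: FrequencyTable,
    partition: Optional[Mapping[str, str]] = None,
    categories: Optional[Sequence[str]] = None,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Exact east/west asymmetry test for each haplogroup category.

    Populations are split per ``partition`` (default: continent-near islands
    east, the rest west); ``exclude`` removes populations first, supporting
    re-tests with outlier islands dropped. Each category is tested against
    all others pooled; categories absent from the table (or with zero total)
    are skipped with a warning.
    """
    partition = dict(DEFAULT_PARTITION if partition is None else partition)
    pops = [p for p in freqs.populations if p not in set(exclude)]
    missing = [p for p in pops if p not in partition]
    if missing:
        raise ValueError(f"partition does not cover populations: {missing}")
    east_pops = [p for p in pops if partition[p] == "east"]
    west_pops = [p for p in pops if partition[p] == "west"]
    east_n = int(freqs.counts.loc[east_pops].to_numpy().sum())
    west_n = int(freqs.counts.loc[west_pops].to_numpy().sum())

    rows = []
    for cat in categories if categories is not None else freqs.categories:
        if cat not in freqs.categories:
            warnings.warn(f"category {cat!r} absent from table; skipped")
            continue
        east = int(freqs.counts.loc[east_pops, cat].sum())
        west = int(freqs.counts.loc[west_pops, cat].sum())
        if east + west == 0:
            warnings.warn(f"category {cat!r} has zero total count; skipped")
            continue
        p = fisher_exact_two_tailed(
            ContingencyTable2x2(east, west, east_n - east, west_n - west)
        )
        rows.append({"category": cat, "east": east, "west": west, "p": p})
    return pd.DataFrame(rows, columns=["category", "east", "west", "p"])
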