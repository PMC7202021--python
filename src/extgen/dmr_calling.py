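"""Pairwise CG differentially-methylated-region calling and nested summaries.

A deliberately transparent pairwise caller: per shared CG site the two
samples are compared with a coverage-weighted two-proportion score test
(the score test of a two-group binomial logistic regression with read-count
weights), per-site methylation differences are smoothed with a moving
average weighted by (1 - p) so uncertain sites contribute less, and maximal
same-sign runs of smoothed differences above the delta threshold become
candidate regions, filtered on CG count and length.  Defaults follow the
common pairwise-DMR convention: |delta| >= 0.2, >= 4 CGs, >= 50 bp.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CytosineCallSet

logger = logging.getLogger(__name__)

__all__ = [
    "DmrRecord",
    "DmrSummary",
    "site_scores",
    "smooth_scores",
    "segment_dmrs",
    "call_dmrs",
    "nested_summary",
    "nested_dmr_analysis",
]


@dataclass
class DmrRecord:
    """One differentially methylated region (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    n_cg: int
    delta: float
    p_mean: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("DMR end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DmrSummary:
    """Per-comparison-level aggregate of pairwise DMR calls."""

    comparison_level: str
    n_comparisons: int
    mean_count: float
    mean_delta: float
    mean_length: float
    mean_cg: float


def site_scores(a: CytosineCallSet, b: CytosineCallSet) -> pd.DataFrame:
    """Per-shared-CG-site methylation difference, p-value and read weight.

    Sites present in only one sample are skipped.  delta = p_a - p_b; the
    p-value is the pooled two-proportion score test (equivalent to the score
    test of a coverage-weighted two-group logistic regression); the weight is
    the smaller of the two coverages.
    """
    cols = ["chrom", "pos", "meth", "total"]
    da = a.data.loc[a.data["context"] == "CG", cols]
    db = b.data.loc[b.data["context"] == "CG", cols]
    merged = da.merge(db, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if merged.empty:
        warnings.warn("no shared CG sites between the two samples", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "pos", "delta", "p", "weight"])
    ma, ta = merged["meth_a"].to_numpy(float), merged["total_a"].to_numpy(float)
    mb, tb = merged["meth_b"].to_numpy(float), merged["total_b"].to_numpy(float)
    pa, pb = ma / ta, mb / tb
    pooled = (ma + mb) / (ta + tb)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / ta + 1.0 / tb))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, (pa - pb) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[se == 0] = 1.0  # both samples all-methylated or all-unmethylated
    return pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "delta": pa - pb,
            "p": p,
            "weight": np.minimum(ta, tb),
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def smooth_scores(scores: pd.DataFrame, half_window: int = 2) -> pd.DataFrame:
    """Moving average of delta over +/- ``half_window`` sites, weighted by (1 - p).

    Windows truncate at chromosome boundaries; ``half_window=0`` is the
    identity.  Adds a ``smoothed`` column.
    """
    if half_window < 0:
        raise ValueError("half_window must be non-negative")
    out = scores.copy()
    smoothed = np.empty(len(out))
    for _, idx in out.groupby("chrom", sort=False).groups.items():
        sub = out.loc[idx]
        d = sub["delta"].to_numpy(float)
        w = 1.0 - sub["p"].to_numpy(float)
        if half_window == 0:
            smoothed[out.index.get_indexer(idx)] = d
            continue
        kernel = np.ones(2 * half_window + 1)
        # "full" + slice keeps the window centered even when the chromosome
        # has fewer sites than the kernel
        num = np.convolve(w * d, kernel, mode="full")[half_window : half_window + len(d)]
        den = np.convolve(w, kernel, mode="full")[half_window : half_window + len(d)]
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(den > 0, num / den, 0.0)
        smoothed[out.index.get_indexer(idx)] = s
    out["smoothed"] = smoothed
    return out


def segment_dmrs(
    scores: pd.DataFrame,
    delta_min: float = 0.2,
    minc: int = 4,
    min_len: int = 50,
) -> list[DmrRecord]:
    """Maximal same-sign runs of |smoothed delta| >= delta_min, filtered on size.

    A run must span at least ``minc`` CG sites and ``min_len`` bp.  The
    reported delta is the coverage-weighted mean of the *raw* per-site
    differences over the run and must itself clear ``delta_min``.
    Coordinates are 0-based half-open (input positions are 1-based).
    """
    if "smoothed" not in scores.columns:
        raise ValueError("scores must be smoothed first (smooth_scores)")
    records: list[DmrRecord] = []
    for chrom, sub in scores.groupby("chrom", sort=False):
        s = sub["smoothed"].to_numpy(float)
        d = sub["delta"].to_numpy(float)
        w = sub["weight"].to_numpy(float)
        p = sub["p"].to_numpy(float)
        pos = sub["pos"].to_numpy(int)
        active = np.abs(s) >= delta_min
        sign = np.sign(s)
        i = 0
        n = len(sub)
        while i < n:
            if not active[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and active[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            n_cg = j - i + 1
            start = int(pos[i]) - 1
            end = int(pos[j])  # 1-based inclusive -> 0-based half-open
            length = end - start
            wsum = w[i : j + 1].sum()
            delta = float(np.average(d[i : j + 1], weights=w[i : j + 1])) if wsum > 0 else 0.0
            if n_cg >= minc and length >= min_len and abs(delta) >= delta_min:
                records.append(
                    DmrRecord(
                        chrom=str(chrom),
                        start=start,
                        end=end,
                        n_cg=n_cg,
                        delta=delta,
                        p_mean=float(p[i : j + 1].mean()),
                    )
                )
            i = j + 1
    return records


def call_dmrs(
    a: CytosineCallSet,
    b: CytosineCallSet,
    delta_min: float = 0.2,
    minc: int = 4,
    min_len: int = 50,
    half_window: int = 2,
) -> list[DmrRecord]:
    """Score, smooth and segment one pairwise comparison."""
    scores = site_scores(a, b)
    if scores.empty:
        return []
    return segment_dmrs(
        smooth_scores(scores, half_window=half_window),
        delta_min=delta_min,
        minc=minc,
        min_len=min_len,
    )


def nested_summary(dmr_sets: dict[str, list[list[DmrRecord]]]) -> list[DmrSummary]:
    """Aggregate pairwise DMR lists per comparison level.

    ``mean_count`` averages the number of DMRs over comparisons; delta (as
    magnitude), length and CG count average over all regions of the level.
    Levels with zero comparisons are omitted with a warning.
    """
    summaries: list[DmrSummary] = []
    for level, comparisons in dmr_sets.items():
        if not comparisons:
            warnings.warn(f"comparison level {level!r} has no pairs; omitted", stacklevel=2)
            continue
        counts = [len(c) for c in comparisons]
        pooled = [r for c in comparisons for r in c]
        if pooled:
            mean_delta = float(np.mean([abs(r.delta) for r in pooled]))
            mean_length = float(np.mean([r.length for r in pooled]))
            mean_cg = float(np.mean([r.n_cg for r in pooled]))
        else:
            mean_delta = mean_length = mean_cg = float("nan")
        summaries.append(
            DmrSummary(
                comparison_level=level,
                n_comparisons=len(comparisons),
                mean_count=float(np.mean(counts)),
                mean_delta=mean_delta,
                mean_length=mean_length,
                mean_cg=mean_cg,
            )
        )
    return summaries


def nested_dmr_analysis(
    plant_calls: dict[str, CytosineCallSet],
    accession_map: dict[str, str],
    family_map: dict[str, str],
    max_pairs_per_level: int | None = None,
    rng: np.random.Generator | None = None,
    **thresholds,
) -> tuple[list[DmrSummary], dict[str, list[list[DmrRecord]]]]:
    """Replicate / intra-family / inter-family pairwise DMR comparison.

    Replicate-level comparisons pair individual plants of the same accession;
    accession-level comparisons (within and between families) pair
    replicate-pooled call sets.  All pairs are enumerated; with
    ``max_pairs_per_level`` a random subset is drawn per level.
    """
    from .methylation_similarity import pool_replicates

    replicate_pairs = []
    by_acc: dict[str, list[str]] = {}
    for plant in plant_calls:
        by_acc.setdefault(accession_map[plant], []).append(plant)
    for plants in by_acc.values():
        replicate_pairs.extend(itertools.combinations(sorted(plants), 2))

    pooled = pool_replicates(
        list(plant_calls.values()),
        {p: accession_map[p] for p in plant_calls},
    )
    accs = sorted(pooled)
    intra, inter = [], []
    for x, y in itertools.combinations(accs, 2):
        (intra if family_map[x] == family_map[y] else inter).append((x, y))

    levels = {"replicate": replicate_pairs, "intra-family": intra, "inter-family": inter}
    if max_pairs_per_level is not None:
        rng = rng or np.random.default_rng()
        for name, pairs in levels.items():
            if len(pairs) > max_pairs_per_level:
                idx = rng.choice(len(pairs), size=max_pairs_per_level, replace=False)
                levels[name] = [pairs[i] for i in sorted(idx)]

    dmr_sets: dict[str, list[list[DmrRecord]]] = {}
    for name, pairs in levels.items():
        results = []
        for x, y in pairs:
            if name == "replicate":
                results.append(call_dmrs(plant_calls[x], plant_calls[y], **thresholds))
            else:
                results.append(call_dmrs(pooled[x], pooled[y], **thresholds))
        dmr_sets[name] = results
    return nested_summary(dmr_sets), dmr_sets


def dmrs_to_bed(records: list[DmrRecord]) -> pd.DataFrame:
    """BED6-compatible frame: name is sequential, score is 1000|delta| capped."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "name": [f"dmr_{i + 1}" for i in range(len(records))],
            "score": [min(1000, int(round(1000 * abs(r.delta)))) for r in records],
            "strand": ["." for _ in records],
        }
    )
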