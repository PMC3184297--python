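"""Decoy-set performance measures, function comparison, and parameter search.

Five measures characterize native recognition (Rank_nat, RMSD_best,
Z_nat, CC_nat, FE_nat over all structures including the native) and
eight characterize decoy discrimination (R_B1, R_B10, RMSD_decoy,
Z_decoy, CC_decoy, FE_decoy, log(P_B1), log(P_B10) over decoys only).
All ranks are competition ("minimum") ranks; Z-scores use the sample
standard deviation and are oriented so better-than-mean structures give
positive values; fraction enrichment uses k = ceil(0.1 N) with the
native-count convention of each measure family.  Undefined measures
(zero score variance, constant RMSD) are reported as NaN and excluded
pairwise from aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from itertools import product
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .potential import (LoCoParams, PotentialDatabase, accumulate_counts,
                        compile_potential)
from .scoring import score_structure
from .structures import DecoySet, MainChainStructure

METRIC_FIELDS = ("rank_nat", "rmsd_best", "z_nat", "cc_nat", "fe_nat",
                 "r_b1", "r_b10", "rmsd_decoy", "z_decoy", "cc_decoy",
                 "fe_decoy", "log_p_b1", "log_p_b10")


@dataclass
class SetMetrics:
    """The 13 per-decoy-set performance measures (fe_* in %, rmsd in Å)."""

    rank_nat: float = math.nan
    rmsd_best: float = math.nan
    z_nat: float = math.nan
    cc_nat: float = math.nan
    fe_nat: float = math.nan
    r_b1: float = math.nan
    r_b10: float = math.nan
    rmsd_decoy: float = math.nan
    z_decoy: float = math.nan
    cc_decoy: float = math.nan
    fe_decoy: float = math.nan
    log_p_b1: float = math.nan
    log_p_b10: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _min_rank(value: float, values: np.ndarray) -> int:
    """Competition rank of value among values (1 = best, ties -> min)."""
    return 1 + int(np.sum(values < value))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def _zscore_of(best: float, values: np.ndarray) -> float:
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        return math.nan
    return float((np.mean(values) - best) / sd)


def _fraction_enrichment(scores: np.ndarray, rmsds: np.ndarray) -> float:
    n = len(scores)
    k = math.ceil(0.1 * n)
    by_rmsd = set(np.argsort(rmsds, kind="stable")[:k].tolist())
    by_score = set(np.argsort(scores, kind="stable")[:k].tolist())
    return 100.0 * len(by_rmsd & by_score) / k


def native_metrics(scores: Sequence[float], rmsds: Sequence[float],
                   native_index: int = 0) -> tuple[float, float, float, float, float]:
    """(rank_nat, rmsd_best, z_nat, cc_nat, fe_nat) over all structures.

    ``scores``/``rmsds`` include the native at ``native_index``; lower
    scores are better.
    """
    scores = np.asarray(scores, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 structures")
    rank_nat = _min_rank(scores[native_index], scores)
    rmsd_best = float(rmsds[np.argmin(scores)])
    z_nat = _zscore_of(scores[native_index], scores)
    cc_nat = _pearson(scores, rmsds)
    fe_nat = _fraction_enrichment(scores, rmsds)
    return float(rank_nat), rmsd_best, z_nat, cc_nat, fe_nat


def decoy_metrics(scores: Sequence[float], rmsds: Sequence[float]
                  ) -> tuple[float, float, float, float, float, float, float, float]:
    """(r_b1, r_b10, rmsd_decoy, z_decoy, cc_decoy, fe_decoy,
    log_p_b1, log_p_b10) over decoys only (native excluded by caller)."""
    scores = np.asarray(scores, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 decoys")
    best = int(np.argmin(scores))
    r_b1 = _min_rank(rmsds[best], rmsds)
    top10 = np.argsort(scores, kind="stable")[:10]  # all of them when n < 10
    r_b10 = min(_min_rank(rmsds[t], rmsds) for t in top10)
    rmsd_decoy = float(rmsds[best])
    z_decoy = _zscore_of(scores[int(np.argmin(rmsds))], scores)
    cc_decoy = _pearson(scores, rmsds)
    fe_decoy = _fraction_enrichment(scores, rmsds)
    return (float(r_b1), float(r_b10), rmsd_decoy, z_decoy, cc_decoy,
            fe_decoy, math.log10(r_b1 / n), math.log10(r_b10 / n))


def metrics_from_scores(native_score: float, decoy_scores: Sequence[float],
                        decoy_rmsds: Sequence[float]) -> SetMetrics:
    """Assemble all 13 measures from a scored decoy set (native RMSD 0)."""
    all_scores = np.concatenate([[native_score], decoy_scores])
    all_rmsds = np.concatenate([[0.0], decoy_rmsds])
    nm = native_metrics(all_scores, all_rmsds, native_index=0)
    dm = decoy_metrics(decoy_scores, decoy_rmsds)
    return SetMetrics(*nm, *dm)


def evaluate_decoy_set(db: PotentialDatabase, dset: DecoySet) -> SetMetrics:
    """Score every member of a decoy set with the potential and measure it."""
    native_score = score_structure(db, dset.native).total
    decoy_scores = [score_structure(db, d).total for d in dset.decoys]
    return metrics_from_scores(native_score, decoy_scores, dset.decoy_rmsds())


def evaluate_with_scorer(scorer: Callable[[list[MainChainStructure]], dict[str, float]],
                         dset: DecoySet, ascending: bool = True) -> SetMetrics:
    """Measure a set under any scorer mapping structures to scores.

    ``scorer`` sees the whole set at once (set-relative functions like
    the ω baseline need that); ``ascending=False`` flips the sign so
    that larger raw scores rank first.
    """
    members = [dset.native] + dset.decoys
    raw = scorer(members)
    sign = 1.0 if ascending else -1.0
    return metrics_from_scores(sign * raw[dset.native.id],
                               [sign * raw[d.id] for d in dset.decoys],
                               dset.decoy_rmsds())


def aggregate(per_set: Sequence[SetMetrics]) -> tuple[SetMetrics, dict[str, int]]:
    """Field-wise arithmetic means, NaN excluded pairwise, with counts."""
    if not per_set:
        raise ValueError("no sets to aggregate")
    means = {}
    counts = {}
    for name in METRIC_FIELDS:
        vals = np.array([getattr(m, name) for m in per_set], dtype=float)
        ok = ~np.isnan(vals)
        counts[name] = int(ok.sum())
        means[name] = float(np.mean(vals[ok])) if ok.any() else math.nan
    return SetMetrics(**means), counts


def metrics_table(per_set: dict[str, SetMetrics]) -> pd.DataFrame:
    """One row per decoy set plus an 'aggregate' mean row."""
    rows = {name: m.as_dict() for name, m in per_set.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    agg, _ = aggregate(list(per_set.values()))
    df.loc["aggregate"] = agg.as_dict()
    df.index.name = "decoy_set"
    return df


def wilcoxon_compare(r_b1_a: Sequence[float], r_b1_b: Sequence[float],
                     paired: bool = True) -> tuple[float, bool]:
    """One-tailed p-value for "function A's rank distribution is lower".

    Paired mode (the default; both functions scored the same sets) uses
    the Wilcoxon signed-rank test with Pratt handling of zero
    differences: exact null distribution when n <= 25 with no zeros or
    tied |differences|, normal approximation with continuity correction
    otherwise.  Unpaired mode falls back to the rank-sum test.  Returns
    (p, degenerate): all-zero differences give p = 1.0 flagged.
    """
    a = np.asarray(r_b1_a, dtype=float)
    b = np.asarray(r_b1_b, dtype=float)
    if not paired:
        res = stats.mannwhitneyu(a, b, alternative="less")
        return float(res.pvalue), False
    if len(a) != len(b):
        raise ValueError("paired comparison needs equal-length samples")
    d = a - b
    if np.all(d == 0):
        return 1.0, True
    nz = d[d != 0]
    exact_ok = (len(nz) <= 25 and not np.any(d == 0)
                and len(np.unique(np.abs(nz))) == len(nz))
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(a, b, zero_method="pratt", alternative="less",
                         correction=True, method=method)
    return float(res.pvalue), False


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid: defaults are the full 84-version search space
    (cutoffs 8–20Å step 2, 1–4 excluded neighbors, 1–3x penalty)."""

    cutoffs: tuple[float, ...] = (8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0)
    exclusions: tuple[int, ...] = (1, 2, 3, 4)
    penalty_mults: tuple[float, ...] = (1.0, 2.0, 3.0)

    def __post_init__(self):
        if not (self.cutoffs and self.exclusions and self.penalty_mults):
            raise ValueError("grid lists must be non-empty")
        if min(self.cutoffs) <= 0 or min(self.penalty_mults) <= 0:
            raise ValueError("grid values must be positive")


def parameter_grid(spec: GridSpec = GridSpec()) -> list[LoCoParams]:
    """Cartesian product of the grid, cutoff-major deterministic order."""
    return [LoCoParams(cutoff=c, exclude_neighbors=e, penalty_mult=m)
            for c, e, m in product(spec.cutoffs, spec.exclusions,
                                   spec.penalty_mults)]


def _fold_partition(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random near-equal folds: sizes differ by at most one."""
    idx = rng.permutation(n)
    base, extra = divmod(n, folds)
    out, start = [], 0
    for f in range(folds):
        size = base + (1 if f < extra else 0)
        out.append(np.sort(idx[start:start + size]))
        start += size
    return out


def cross_validate(grid: Sequence[LoCoParams],
                   training_sets: Sequence[DecoySet],
                   corpus: Sequence[MainChainStructure],
                   folds: int = 10, repeats: int = 10, seed: int = 0,
                   rmsd_matrix: Optional[np.ndarray] = None,
                   ) -> tuple[LoCoParams, dict]:
    """Repeated k-fold selection of the best-performing parameter version.

    A potential is trained on ``corpus`` under every parameter version
    and each version's RMSD_decoy (CA RMSD of its best-scoring decoy) is
    computed on every training set.  Within each repeat the sets are
    randomly partitioned into near-equal folds; for each fold the
    version minimizing mean RMSD_decoy over the held-in sets is selected
    and charged with its held-out performance, and the repeat's winner
    is the selected version with the lowest mean held-out RMSD_decoy.
    The final winner is the modal repeat winner (ties broken by mean
    held-out performance).  Deterministic given ``seed``.

    ``rmsd_matrix`` (n_versions x n_sets) short-circuits the training
    and scoring pass; it exists for testing and for callers that have
    already evaluated the grid.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if len(training_sets) < folds:
        raise ValueError(f"need at least {folds} decoy sets for {folds}-fold CV")
    if rmsd_matrix is None:
        rmsd_matrix = np.empty((len(grid), len(training_sets)))
        for vi, params in enumerate(grid):
            db = compile_potential(accumulate_counts(corpus, params))
            for si, dset in enumerate(training_sets):
                rmsd_matrix[vi, si] = evaluate_decoy_set(db, dset).rmsd_decoy
    rmsd_matrix = np.asarray(rmsd_matrix, dtype=float)

    report: dict = {"repeats": [], "folds": folds, "n_versions": len(grid),
                    "n_sets": len(training_sets), "seed": seed}
    repeat_winners: list[int] = []
    repeat_winner_scores: list[float] = []
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        fold_idx = _fold_partition(len(training_sets), folds, rng)
        fold_records = []
        heldout_by_version: dict[int, list[float]] = {}
        for f, held_out in enumerate(fold_idx):
            held_in = np.setdiff1d(np.arange(len(training_sets)), held_out)
            means_in = rmsd_matrix[:, held_in].mean(axis=1)
            v_sel = int(np.argmin(means_in))
            heldout_mean = float(rmsd_matrix[v_sel, held_out].mean())
            heldout_by_version.setdefault(v_sel, []).append(heldout_mean)
            fold_records.append({"fold": f, "selected_version": v_sel,
                                 "held_in_mean_rmsd": float(means_in[v_sel]),
                                 "held_out_mean_rmsd": heldout_mean,
                                 "held_out_sets": held_out.tolist()})
        cand = {v: float(np.mean(ms)) for v, ms in heldout_by_version.items()}
        winner = min(cand, key=lambda v: (cand[v], v))
        repeat_winners.append(winner)
        repeat_winner_scores.append(cand[winner])
        report["repeats"].append({"repeat": rep, "winner_version": winner,
                                  "winner_held_out_mean": cand[winner],
                                  "folds": fold_records})
    # modal winner across repeats; ties broken by best mean held-out score
    tally: dict[int, list[float]] = {}
    for w, s in zip(repeat_winners, repeat_winner_scores):
        tally.setdefault(w, []).append(s)
    final = min(tally, key=lambda v: (-len(tally[v]), float(np.mean(tally[v])), v))
    report["winner_version"] = final
    report["winner_params"] = grid[final].to_dict()
    return grid[final], report
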