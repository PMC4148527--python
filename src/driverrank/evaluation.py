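"""Benchmarking and parameter-tuning utilities.

Top-N metrics against a gold-standard driver list:

    precision = |top-N altered genes in gold| / N
    recall    = |top-N altered genes in gold| / |altered gold genes in cohort|
    F1        = harmonic mean (0 when precision + recall = 0)

plus cohort-subsampling experiments, grid-search tuners for the
propagation parameter ``mu`` and the Condorcet penalty ``delta``, and
the rare-driver frequency-distribution comparison between patient
subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .condorcet import AlterationCatalog, condorcet_aggregate
from .drivers import DriverCallSet
from .network import GeneNetwork
from .rank import rank_cohort

__all__ = [
    "precision_recall_f1",
    "metric_curve",
    "subsample_experiment",
    "tune_mu",
    "tune_delta",
    "rare_driver_distribution",
    "TuningResult",
    "RareDriverDistribution",
]


def precision_recall_f1(
    ranked_genes: Sequence[str],
    gold: Iterable[str],
    mutated_gold_total: int,
    n: int,
) -> tuple[float, float | None, float | None]:
    """Top-``n`` precision/recall/F1 of a ranked gene list.

    ``mutated_gold_total`` is the number of distinct gold-standard
    genes altered anywhere in the cohort (the recall denominator).
    Recall and F1 are None when that denominator is zero.
    """
    if n < 0 or n > len(ranked_genes):
        raise ValueError(f"n={n} outside [0, {len(ranked_genes)}]")
    if mutated_gold_total < 0:
        raise ValueError("mutated_gold_total must be >= 0")
    gold = set(gold)
    hits = sum(1 for g in ranked_genes[:n] if g in gold)
    precision = hits / n if n > 0 else 0.0
    if mutated_gold_total == 0:
        return precision, None, None
    recall = hits / mutated_gold_total
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def metric_curve(
    ranked_genes: Sequence[str],
    gold: Iterable[str],
    mutated_gold_total: int,
    n_values: Sequence[int],
) -> pd.DataFrame:
    """Precision/recall/F1 at each top-N cutoff, as a tidy frame."""
    gold = set(gold)
    rows = []
    for n in n_values:
        p, r, f1 = precision_recall_f1(ranked_genes, gold, mutated_gold_total, n)
        rows.append({"n": n, "precision": p, "recall": r, "f1": f1})
    return pd.DataFrame(rows)


def _mutated_gold_total(catalog: AlterationCatalog, gold: set[str]) -> int:
    return len(set(catalog.table["gene"]) & gold)


def subsample_experiment(
    network: GeneNetwork,
    tumor: pd.DataFrame,
    normal: pd.Series | pd.DataFrame,
    catalog: AlterationCatalog,
    gold: Iterable[str],
    sizes: Sequence[int] = (10, 20, 50, 100),
    reps: int = 10,
    top_n: int = 30,
    mu: float = 3.0,
    delta: float = 0.85,
    seed: int | None = None,
) -> pd.DataFrame:
    """Precision at top-``top_n`` on random patient subsets.

    For each cohort size, ``reps`` random subsets are drawn without
    replacement, the full rank-then-aggregate pipeline is run on each,
    and the mean and sd of the top-N precision against ``gold`` are
    reported.  Per-patient rankings do not depend on which other
    patients are in the subset, so they are computed once for the whole
    cohort and reused across subsets.
    """
    gold = set(gold)
    patients = list(tumor.columns)
    for size in sizes:
        if size > len(patients):
            raise ValueError(f"subset size {size} exceeds cohort size {len(patients)}")
    rng = np.random.default_rng(seed)
    percentiles, _ = rank_cohort(network, tumor, normal, mu=mu)
    rows = []
    for size in sizes:
        precisions = []
        for _ in range(reps):
            chosen = list(rng.choice(patients, size=size, replace=False))
            sub = catalog.restrict(chosen)
            if len(sub.candidate_genes()) < 2:
                precisions.append(0.0)
                continue
            agg = condorcet_aggregate(percentiles, sub, delta=delta)
            k = min(top_n, len(agg.order))
            p, _, _ = precision_recall_f1(agg.order, gold, max(_mutated_gold_total(sub, gold), 0), k)
            precisions.append(p)
        rows.append(
            {
                "size": size,
                "reps": reps,
                "precision_mean": float(np.mean(precisions)),
                "precision_sd": float(np.std(precisions, ddof=1)) if reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TuningResult:
    """Grid-search outcome for a scalar parameter."""

    best: float
    table: pd.DataFrame  # columns: parameter value, score


def _sample_patients(patients: list[str], n_samples: int, rng: np.random.Generator) -> list[str]:
    if n_samples >= len(patients):
        return list(patients)
    return list(rng.choice(patients, size=n_samples, replace=False))


def tune_mu(
    candidate_mus: Sequence[float],
    network: GeneNetwork,
    tumor: pd.DataFrame,
    normal: pd.Series | pd.DataFrame,
    catalog: AlterationCatalog,
    gold: Iterable[str],
    n_samples: int = 100,
    seed: int | None = None,
) -> TuningResult:
    """Choose ``mu`` maximizing the mean percentile of altered gold genes.

    For each candidate the sampled patients are ranked and the score is
    the mean percentile, over sampled patients, of the gold-standard
    genes altered in that patient.  Ties pick the smallest ``mu``.
    """
    candidates = sorted(float(m) for m in candidate_mus)
    if not candidates:
        raise ValueError("no candidate mu values")
    gold = set(gold)
    if _mutated_gold_total(catalog, gold) == 0:
        raise ValueError("no gold-standard gene is altered in the cohort")
    rng = np.random.default_rng(seed)
    sampled = _sample_patients(list(tumor.columns), n_samples, rng)
    rows = []
    for mu in candidates:
        percentiles, _ = rank_cohort(network, tumor[sampled], normal, mu=mu)
        per_patient = []
        for patient in sampled:
            gold_altered = sorted(
                (catalog.genes_for(patient) & gold) & set(percentiles.index)
            )
            if gold_altered:
                per_patient.append(float(percentiles.loc[gold_altered, patient].mean()))
        rows.append({"mu": mu, "score": float(np.mean(per_patient)) if per_patient else 0.0})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["score"].idxmax(), "mu"])  # idxmax: first (smallest) on ties
    return TuningResult(best=best, table=table)


def tune_delta(
    candidate_deltas: Sequence[float],
    percentiles: pd.DataFrame,
    catalog: AlterationCatalog,
    gold: Iterable[str],
    n_samples: int = 100,
    top_n: int = 30,
    seed: int | None = None,
) -> TuningResult:
    """Choose the Condorcet penalty ``delta`` maximizing top-N precision.

    For each candidate, the sampled patients are Condorcet-aggregated
    and the precision of the top ``top_n`` against ``gold`` is scored.
    Ties pick the smallest ``delta``.
    """
    candidates = sorted(float(d) for d in candidate_deltas)
    if not candidates:
        raise ValueError("no candidate delta values")
    if any(not 0.0 <= d <= 1.0 for d in candidates):
        raise ValueError("delta candidates must lie in [0, 1]")
    gold = set(gold)
    if _mutated_gold_total(catalog, gold) == 0:
        raise ValueError("no gold-standard gene is altered in the cohort")
    rng = np.random.default_rng(seed)
    sampled = _sample_patients(list(catalog.patients), n_samples, rng)
    sub = catalog.restrict(sampled)
    rows = []
    for delta in candidates:
        agg = condorcet_aggregate(percentiles, sub, delta=delta)
        k = min(top_n, len(agg.order))
        p, _, _ = precision_recall_f1(agg.order, gold, max(_mutated_gold_total(sub, gold), 1), k)
        rows.append({"delta": delta, "score": p})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["score"].idxmax(), "delta"])
    return TuningResult(best=best, table=table)


@dataclass
class RareDriverDistribution:
    """Rare-driver frequency distribution per subgroup, with pair tests."""

    proportions: pd.DataFrame  # subgroup x bin: fraction of patients with a call in the bin
    counts: pd.DataFrame  # subgroup x bin: patient counts
    pairwise: pd.DataFrame  # columns: group_a, group_b, chi2, p_value, df


def rare_driver_distribution(
    call_sets_by_subgroup: Mapping[str, Iterable[DriverCallSet]],
    freq_cutoffs: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05),
) -> RareDriverDistribution:
    """Compare low-frequency driver burden across patient subgroups.

    Frequency bins are non-cumulative half-open intervals
    ``[0, c1), [c1, c2), ...`` over the supplied cutoffs.  For each
    subgroup and bin, the proportion of patient samples with at least
    one called driver whose cohort alteration frequency falls in the
    bin is reported.  Each subgroup pair is tested with a chi-square on
    the binned patient counts (no continuity correction).
    """
    cutoffs = sorted(float(c) for c in freq_cutoffs)
    if len(call_sets_by_subgroup) < 2:
        raise ValueError("need at least two subgroups")
    edges = [0.0] + cutoffs
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]

    counts: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for name, call_sets in call_sets_by_subgroup.items():
        call_sets = list(call_sets)
        if not call_sets:
            raise ValueError(f"subgroup {name!r} has no patients")
        binned = np.zeros(len(labels), dtype=int)
        total_calls = 0
        for cs in call_sets:
            in_bin = np.zeros(len(labels), dtype=bool)
            for call in cs.calls:
                total_calls += 1
                for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
                    if lo <= call.frequency < hi:
                        in_bin[k] = True
            binned += in_bin
        if total_calls == 0:
            warnings.warn(f"subgroup {name!r} has no driver calls; excluded")
            continue
        counts[name] = binned
        sizes[name] = len(call_sets)
    if len(counts) < 2:
        raise ValueError("fewer than two subgroups with driver calls")

    count_df = pd.DataFrame(counts, index=labels).T
    prop_df = count_df.div(pd.Series(sizes), axis=0)

    rows = []
    for a, b in combinations(count_df.index, 2):
        table = count_df.loc[[a, b]].to_numpy()
        keep = table.sum(axis=0) > 0  # drop bins empty in both groups
        table = table[:, keep]
        if table.shape[1] < 2:
            chi2, p, dof = 0.0, 1.0, 0
        else:
            chi2, p, dof, _ = chi2_contingency(table, correction=False)
        rows.append(
            {"group_a": a, "group_b": b, "chi2": float(chi2), "p_value": float(p), "df": int(dof)}
        )
    return RareDriverDistribution(
        proportions=prop_df, counts=count_df, pairwise=pd.DataFrame(rows)
    )
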