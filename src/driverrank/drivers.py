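"""Driver-gene calling: personalized, rare and novel drivers, plus CNV events.

Personalized drivers in one patient are altered genes that clear two
independent hurdles:

1. a per-patient percentile cutoff chosen by a maximally selected rank
   statistic — the cutoff on the patient's percentile ranking that
   maximizes the (continuity-uncorrected) 2x2 chi-square association
   between being above/below the cutoff and membership in a
   gold-standard driver list;
2. Chauvenet's criterion applied one-sidedly to the gene's percentile
   ranks across the whole cohort: the value is an outlier when
   ``n * P(Z > z) < 0.5`` with ``z`` the standardized rank.

A personalized driver altered in fewer than 2% of patients is a
personalized *rare* driver.  Cohort-level novel drivers are genes in
the top 30 of the aggregate ranking, altered in more than 2% of
patients, and absent from the gold standard.  Copy-number events with
at least a two-fold change and a concordant expression change are
converted into alteration records so they flow through the same
machinery as coding mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal

from .condorcet import AggregateRanking, AlterationCatalog

__all__ = [
    "MaxstatCutoff",
    "maxstat_cutoff",
    "ChauvenetResult",
    "chauvenet_high",
    "DriverCall",
    "DriverCallSet",
    "call_personalized_drivers",
    "classify_novel_drivers",
    "cnv_to_alterations",
]


@dataclass
class MaxstatCutoff:
    """A maximally selected rank-statistic cutoff on percentile ranks."""

    cutoff: float
    statistic: float
    low_confidence: bool
    n_gold: int
    n_other: int


def _chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Continuity-uncorrected chi-square of a 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def maxstat_cutoff(
    percentiles: pd.Series,
    gold: Iterable[str],
    span: tuple[float, float] = (0.10, 0.90),
) -> MaxstatCutoff:
    """Pick the percentile cutoff best separating gold from other genes.

    Candidate cutoffs are the observed percentile values whose quantile
    position lies within ``span`` (central 10th-90th range by default,
    the usual guard against degenerate extreme splits).  For each
    candidate ``c`` the 2x2 table (percentile >= c versus below, gold
    versus non-gold) is scored by the uncorrected chi-square; the
    smallest maximizing cutoff is returned.  A flat statistic (no
    separation signal) is flagged ``low_confidence``.
    """
    gold = set(gold)
    values = percentiles.to_numpy(dtype=float)
    is_gold = np.array([g in gold for g in percentiles.index], dtype=bool)
    n_gold = int(is_gold.sum())
    n_other = int((~is_gold).sum())
    if n_gold == 0:
        raise ValueError(
            "no gold-standard genes present in the ranking; "
            "supply an explicit cutoff instead"
        )
    if n_other == 0:
        raise ValueError("all genes are gold-standard; cutoff is undefined")
    lo, hi = np.quantile(values, span)
    candidates = np.unique(values[(values >= lo) & (values <= hi)])
    if candidates.size == 0:
        candidates = np.unique(values)
    best_cut, best_stat = None, -1.0
    for c in candidates:  # ascending, so ties keep the smallest cutoff
        above = values >= c
        stat = _chi2_2x2(
            int((above & is_gold).sum()),
            int((above & ~is_gold).sum()),
            int((~above & is_gold).sum()),
            int((~above & ~is_gold).sum()),
        )
        if stat > best_stat:
            best_cut, best_stat = float(c), float(stat)
    return MaxstatCutoff(
        cutoff=best_cut,
        statistic=best_stat,
        low_confidence=best_stat <= 0.0,
        n_gold=n_gold,
        n_other=n_other,
    )


@dataclass
class ChauvenetResult:
    """One-sided Chauvenet outlier decision.

    ``is_outlier`` is None when the test is not callable (fewer than
    three cohort values, or zero spread).
    """

    is_outlier: bool | None
    z: float
    expected_extreme: float
    n: int

    @property
    def callable(self) -> bool:
        return self.is_outlier is not None


def chauvenet_high(values, value: float) -> ChauvenetResult:
    """Flag ``value`` as a significantly *high* outlier among ``values``.

    One-sided Chauvenet: outlier iff ``n * P(Z > z) < 0.5`` where
    ``z = (value - mean) / sd`` (sample sd).  Values at or below the
    mean are never flagged.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 3:
        return ChauvenetResult(None, float("nan"), float("nan"), n)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        return ChauvenetResult(None, float("nan"), float("nan"), n)
    z = (float(value) - mean) / sd
    expected = n * float(_normal.sf(z))
    return ChauvenetResult(expected < 0.5, z, expected, n)


@dataclass
class DriverCall:
    """One personalized driver call in one patient."""

    gene: str
    percentile: float
    chauvenet_z: float
    classification: str  # "personalized" or "personalized_rare"
    categories: tuple[str, ...]
    frequency: float
    known: bool  # present in the gold-standard list


@dataclass
class DriverCallSet:
    """All personalized driver calls for one patient."""

    patient_id: str
    calls: list[DriverCall]
    cutoff: float
    cutoff_low_confidence: bool = False

    def genes(self) -> list[str]:
        return [c.gene for c in self.calls]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": self.patient_id,
                "gene": [c.gene for c in self.calls],
                "percentile": [c.percentile for c in self.calls],
                "cutoff": self.cutoff,
                "chauvenet_z": [c.chauvenet_z for c in self.calls],
                "class": [c.classification for c in self.calls],
                "categories": [",".join(c.categories) for c in self.calls],
                "frequency": [c.frequency for c in self.calls],
                "known": [c.known for c in self.calls],
            }
        )


def call_personalized_drivers(
    patient_id: str,
    percentiles: pd.DataFrame,
    catalog: AlterationCatalog,
    gold: Iterable[str] | None = None,
    cutoff: float | None = None,
    rare_threshold: float = 0.02,
) -> DriverCallSet:
    """Call personalized drivers for one patient.

    An altered gene is called iff its percentile in this patient is at
    or above the per-patient cutoff (maximally selected rank statistic
    against ``gold``, unless an explicit ``cutoff`` is supplied) *and*
    its percentile is a one-sided Chauvenet outlier relative to the
    gene's percentiles across the whole cohort.  Calls with cohort
    alteration frequency below ``rare_threshold`` are classed
    ``personalized_rare``.
    """
    if patient_id not in percentiles.columns:
        raise KeyError(f"no ranking for patient {patient_id!r}")
    patient_pct = percentiles[patient_id]
    low_confidence = False
    if cutoff is None:
        if gold is None:
            raise ValueError("either a gold-standard gene set or an explicit cutoff is required")
        ms = maxstat_cutoff(patient_pct, gold)
        cutoff, low_confidence = ms.cutoff, ms.low_confidence
    gold = set(gold or ())

    calls: list[DriverCall] = []
    for gene in sorted(catalog.genes_for(patient_id)):
        if gene not in patient_pct.index:
            continue
        pct = float(patient_pct.loc[gene])
        if pct < cutoff:
            continue
        cohort = percentiles.loc[gene].to_numpy(dtype=float)
        ch = chauvenet_high(cohort, pct)
        if ch.is_outlier is not True:
            continue
        freq = catalog.frequency(gene)
        calls.append(
            DriverCall(
                gene=gene,
                percentile=pct,
                chauvenet_z=ch.z,
                classification=(
                    "personalized_rare" if freq < rare_threshold else "personalized"
                ),
                categories=tuple(sorted(catalog.categories_for(patient_id, gene))),
                frequency=freq,
                known=gene in gold,
            )
        )
    return DriverCallSet(
        patient_id=patient_id,
        calls=calls,
        cutoff=float(cutoff),
        cutoff_low_confidence=low_confidence,
    )


def classify_novel_drivers(
    aggregate: AggregateRanking,
    catalog: AlterationCatalog,
    gold: Iterable[str],
    top_n: int = 30,
    min_freq: float = 0.02,
) -> list[str]:
    """Cohort-level novel drivers, in aggregate order.

    A novel driver is (1) in the top ``top_n`` of the aggregate
    ranking, (2) altered in strictly more than ``min_freq`` of
    patients, and (3) absent from the gold-standard list.
    """
    gold = set(gold)
    out = []
    for gene in aggregate.order[:top_n]:
        if gene in gold:
            continue
        if catalog.frequency(gene) > min_freq:
            out.append(gene)
    return out


def cnv_to_alterations(
    cnv_log2: pd.DataFrame,
    signed_diff: pd.DataFrame | Mapping[str, pd.Series],
    fold_threshold: float = 2.0,
    expr_sign_required: bool = True,
    min_expr_change: float = 0.0,
) -> pd.DataFrame:
    """Convert gene-level CNV log2 ratios into alteration records.

    A gene-patient pair becomes a ``cnv_amp`` (``cnv_del``) event when
    its |log2 ratio| reaches ``log2(fold_threshold)`` with positive
    (negative) sign and — when ``expr_sign_required`` — the signed
    tumor-minus-normal expression difference has the same sign with
    magnitude above ``min_expr_change``.  Returns a long-format frame
    with columns patient / gene / category, ready to extend an
    :class:`AlterationCatalog` table.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    log2_cut = math.log2(fold_threshold)
    if not isinstance(signed_diff, pd.DataFrame):
        signed_diff = pd.DataFrame(dict(signed_diff))
    rows = []
    for patient in cnv_log2.columns:
        ratios = cnv_log2[patient]
        if not np.isfinite(ratios.to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite CNV log2 ratios for patient {patient!r}")
        for gene, ratio in ratios.items():
            if abs(ratio) < log2_cut:
                continue
            category = "cnv_amp" if ratio > 0 else "cnv_del"
            if expr_sign_required:
                if patient not in signed_diff.columns or gene not in signed_diff.index:
                    continue
                change = float(signed_diff.at[gene, patient])
                if abs(change) <= min_expr_change:
                    continue
                if (change > 0) != (ratio > 0):
                    continue
            rows.append((str(patient), str(gene), category))
    return pd.DataFrame(rows, columns=["patient", "gene", "category"])
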