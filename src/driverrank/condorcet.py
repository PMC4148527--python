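"""Cohort-level rank aggregation by penalized Condorcet voting.

Each patient is a voter whose ballot is the percentile ranking of all
genes in that patient.  For a pair of candidate genes (A, B), only
patients with an alteration in at least one of the two are eligible to
vote on the pair; within an eligible patient the gene that is *not*
altered has its percentile multiplied by a penalty ``delta`` in [0, 1]
(default 0.85), and A wins the patient iff its penalized score is
strictly greater than B's (ties go to B).  Pairwise wins are completed
into a total order by Copeland counting: candidates are sorted by the
number of pairwise contests won, then by summed win margin, then
lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALTERATION_CLASSES",
    "AlterationCatalog",
    "PairwiseResult",
    "AggregateRanking",
    "pairwise_winner",
    "condorcet_aggregate",
]

ALTERATION_CLASSES = ("point_mutation", "indel", "cnv_amp", "cnv_del")

_PATIENT_ALIASES = ("patient", "sample", "sample_id", "tumor_sample_barcode")
_GENE_ALIASES = ("gene", "hugo_symbol", "gene_symbol")
_CLASS_ALIASES = ("category", "class", "classification", "variant_classification")


def _find_column(df: pd.DataFrame, aliases: Sequence[str], what: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    raise ValueError(f"alteration table lacks a {what} column (tried {aliases})")


@dataclass
class AlterationCatalog:
    """Per-patient somatic alteration sets for a cohort.

    ``table`` is a long-format frame with columns ``patient``, ``gene``
    and ``category`` (one of point_mutation / indel / cnv_amp /
    cnv_del).  ``patients`` fixes the cohort: it may include patients
    with no recorded alteration, and it is the denominator of
    alteration frequencies.
    """

    table: pd.DataFrame
    patients: list[str]
    _by_patient: dict[str, set[str]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        table = self.table.copy()
        for col in ("patient", "gene", "category"):
            if col not in table.columns:
                raise ValueError(f"alteration table lacks column {col!r}")
        bad = set(table["category"]) - set(ALTERATION_CLASSES)
        if bad:
            raise ValueError(
                f"unknown alteration classes {sorted(bad)}; "
                f"expected one of {ALTERATION_CLASSES}"
            )
        self.patients = list(dict.fromkeys(self.patients))
        unknown = set(table["patient"]) - set(self.patients)
        if unknown:
            raise ValueError(f"alterations for undeclared patients {sorted(unknown)[:10]}")
        self.table = table.reset_index(drop=True)
        self._by_patient = {p: set() for p in self.patients}
        for p, g in zip(table["patient"], table["gene"]):
            self._by_patient[p].add(g)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_table(cls, source, patients: Iterable[str] | None = None) -> "AlterationCatalog":
        """Build from a MAF-lite TSV (path or DataFrame).

        Recognized columns (case-insensitive): patient/sample/...,
        gene/hugo_symbol, and optionally category/class/...; rows
        without a class column default to ``point_mutation``.
        """
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
        pcol = _find_column(df, _PATIENT_ALIASES, "patient")
        gcol = _find_column(df, _GENE_ALIASES, "gene")
        try:
            ccol = _find_column(df, _CLASS_ALIASES, "category")
            cats = df[ccol].astype(str)
        except ValueError:
            cats = pd.Series(["point_mutation"] * len(df))
        table = pd.DataFrame(
            {
                "patient": df[pcol].astype(str).to_numpy(),
                "gene": df[gcol].astype(str).to_numpy(),
                "category": cats.to_numpy(),
            }
        ).drop_duplicates()
        if patients is None:
            patients = list(dict.fromkeys(table["patient"]))
        return cls(table, list(patients))

    @classmethod
    def from_binary_matrix(cls, matrix: pd.DataFrame, category: str = "point_mutation") -> "AlterationCatalog":
        """Build from a 0/1 genes x patients indicator matrix."""
        rows = []
        for patient in matrix.columns:
            for gene in matrix.index[matrix[patient].astype(bool)]:
                rows.append((str(patient), str(gene), category))
        table = pd.DataFrame(rows, columns=["patient", "gene", "category"])
        return cls(table, [str(c) for c in matrix.columns])

    # -- queries ------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def genes_for(self, patient: str) -> set[str]:
        try:
            return set(self._by_patient[patient])
        except KeyError:
            raise KeyError(f"unknown patient {patient!r}") from None

    def categories_for(self, patient: str, gene: str) -> set[str]:
        sub = self.table
        mask = (sub["patient"] == patient) & (sub["gene"] == gene)
        return set(sub.loc[mask, "category"])

    def candidate_genes(self) -> list[str]:
        """Genes altered in at least one patient, sorted."""
        return sorted(set(self.table["gene"]))

    def frequencies(self) -> pd.Series:
        """Fraction of cohort patients carrying each altered gene."""
        counts = (
            self.table[["patient", "gene"]]
            .drop_duplicates()
            .groupby("gene")
            .size()
        )
        return (counts / self.n_patients).rename("frequency")

    def frequency(self, gene: str) -> float:
        n = self.table.loc[self.table["gene"] == gene, "patient"].nunique()
        return n / self.n_patients

    def restrict(self, patients: Sequence[str]) -> "AlterationCatalog":
        """Sub-catalog over a patient subset (frequencies recomputed)."""
        patients = list(patients)
        missing = set(patients) - set(self.patients)
        if missing:
            raise KeyError(f"unknown patients {sorted(missing)[:10]}")
        table = self.table[self.table["patient"].isin(set(patients))]
        return AlterationCatalog(table.copy(), patients)

    def mutation_matrix(self, genes: Sequence[str], patients: Sequence[str] | None = None) -> np.ndarray:
        """Boolean genes x patients alteration-indicator matrix."""
        patients = list(patients) if patients is not None else self.patients
        mat = np.zeros((len(genes), len(patients)), dtype=bool)
        gidx = {g: i for i, g in enumerate(genes)}
        for j, p in enumerate(patients):
            for g in self.genes_for(p):
                i = gidx.get(g)
                if i is not None:
                    mat[i, j] = True
        return mat


@dataclass
class PairwiseResult:
    """Outcome of one pairwise contest between two genes."""

    gene_a: str
    gene_b: str
    wins_a: int
    wins_b: int
    eligible_patients: int

    @property
    def winner(self) -> str | None:
        if self.wins_a > self.wins_b:
            return self.gene_a
        if self.wins_b > self.wins_a:
            return self.gene_b
        return None  # tie (including zero eligible patients)


def _check_pair_inputs(percentiles: pd.DataFrame, catalog: AlterationCatalog, delta: float) -> None:
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta!r}")
    missing = set(catalog.patients) - set(percentiles.columns)
    if missing:
        raise ValueError(f"no percentile ranking for patients {sorted(missing)[:10]}")


def pairwise_winner(
    gene_a: str,
    gene_b: str,
    percentiles: pd.DataFrame,
    catalog: AlterationCatalog,
    delta: float = 0.85,
) -> PairwiseResult:
    """Contest two genes over all eligible patients.

    A patient is eligible iff at least one of the two genes is altered
    in it.  Within an eligible patient each gene's percentile is
    multiplied by ``delta`` if the gene is not altered there; A takes
    the patient iff its penalized score strictly exceeds B's,
    otherwise B does.
    """
    if gene_a == gene_b:
        raise ValueError("pairwise contest requires two distinct genes")
    _check_pair_inputs(percentiles, catalog, delta)
    for g in (gene_a, gene_b):
        if g not in percentiles.index:
            raise ValueError(f"gene {g!r} has no percentile scores")
    wins_a = wins_b = eligible = 0
    for patient in catalog.patients:
        altered = catalog.genes_for(patient)
        a_mut, b_mut = gene_a in altered, gene_b in altered
        if not (a_mut or b_mut):
            continue
        eligible += 1
        score_a = percentiles.at[gene_a, patient] * (1.0 if a_mut else delta)
        score_b = percentiles.at[gene_b, patient] * (1.0 if b_mut else delta)
        if score_a > score_b:
            wins_a += 1
        else:
            wins_b += 1
    return PairwiseResult(gene_a, gene_b, wins_a, wins_b, eligible)


@dataclass
class AggregateRanking:
    """Pairwise-win tally and total order of candidate genes."""

    candidates: list[str]
    wins: pd.DataFrame  # wins.at[a, b] = patients where a beat b
    copeland: pd.Series  # pairwise contests won
    margin: pd.Series  # sum over pairs of (wins_a - wins_b)
    order: list[str]  # best first
    delta: float
    frequency: pd.Series

    def table(self) -> pd.DataFrame:
        """Aggregate ranking as a tidy frame, best gene first."""
        return pd.DataFrame(
            {
                "gene": self.order,
                "copeland_wins": self.copeland.reindex(self.order).to_numpy(),
                "margin": self.margin.reindex(self.order).to_numpy(),
                "aggregate_rank": np.arange(1, len(self.order) + 1),
                "frequency": self.frequency.reindex(self.order).to_numpy(),
            }
        )


def condorcet_aggregate(
    percentiles: pd.DataFrame,
    catalog: AlterationCatalog,
    delta: float = 0.85,
    candidates: Sequence[str] | None = None,
) -> AggregateRanking:
    """Aggregate per-patient percentile rankings into a cohort order.

    Candidates default to all genes altered in at least one patient.
    The result is deterministic: Copeland wins, then summed margin,
    then lexicographic gene symbol.
    """
    _check_pair_inputs(percentiles, catalog, delta)
    if catalog.n_patients < 1:
        raise ValueError("need at least one patient")
    if candidates is None:
        candidates = catalog.candidate_genes()
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate genes to aggregate")
    missing = [g for g in candidates if g not in percentiles.index]
    if missing:
        raise ValueError(f"candidates without percentile scores: {missing[:10]}")

    patients = catalog.patients
    pct = percentiles.loc[candidates, patients].to_numpy(dtype=float)
    mut = catalog.mutation_matrix(candidates, patients)
    penalized = np.where(mut, pct, delta * pct)

    n = len(candidates)
    wins = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        elig = mut[i] | mut[j]
        n_elig = int(elig.sum())
        if n_elig == 0:
            continue
        wa = int((penalized[i][elig] > penalized[j][elig]).sum())
        wins[i, j] = wa
        wins[j, i] = n_elig - wa  # ties within a patient go to the second gene

    beats = wins > wins.T
    copeland = beats.sum(axis=1)
    margin = (wins - wins.T).sum(axis=1)
    order_idx = sorted(
        range(n), key=lambda k: (-copeland[k], -margin[k], candidates[k])
    )
    idx = pd.Index(candidates, name="gene")
    return AggregateRanking(
        candidates=candidates,
        wins=pd.DataFrame(wins, index=idx, columns=idx),
        copeland=pd.Series(copeland, index=idx, name="copeland_wins"),
        margin=pd.Series(margin, index=idx, name="margin"),
        order=[candidates[k] for k in order_idx],
        delta=delta,
        frequency=catalog.frequencies().reindex(idx).fillna(0.0),
    )
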