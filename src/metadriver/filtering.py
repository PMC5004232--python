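"""Somatic variant filtering, mutation matrix, group-specific mutations, burden.

The filtering stage reproduces the standard germline/artifact exclusions used
for tumor–normal exome calls: matched-normal subtraction, common-population
removal (allele frequency strictly above a threshold), removal of synonymous
and unclassifiable SNVs, and restriction to exonic/splice-site territory.

Group-specific mutations are those carried by strictly more than ``min_frac``
of the high-risk (HRM) group and by zero low-risk (LRM) samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HRM, LRM, CohortLabels, VariantRecord

logger = logging.getLogger(__name__)

MutationKey = tuple[str, str]

_EXCLUDED_CLASSES = frozenset({"synonymous", "unknown"})
_KEPT_REGIONS = frozenset({"exon", "splice_site"})


class MutationMatrix:
    """Binary samples × mutations incidence matrix.

    Rows are samples, columns are mutation keys ``(gene, protein_change)``.
    Column and row labels are unique and canonically (lexicographically)
    ordered; all-zero columns are removed on construction.
    """

    def __init__(
        self,
        samples: Sequence[str],
        mutations: Sequence[MutationKey],
        values: np.ndarray,
    ):
        values = np.asarray(values, dtype=np.int8)
        if values.shape != (len(samples), len(mutations)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mutation matrix entries must be binary")
        if len(set(samples)) != len(samples) or len(set(mutations)) != len(mutations):
            raise ValueError("duplicate row or column labels")
        keep = values.sum(axis=0) > 0
        self.samples: list[str] = list(samples)
        self.mutations: list[MutationKey] = [m for m, k in zip(mutations, keep) if k]
        self.values: np.ndarray = values[:, keep]

    @classmethod
    def from_variants(
        cls, variants: Iterable[VariantRecord], labels: CohortLabels
    ) -> "MutationMatrix":
        """Build the incidence matrix from (filtered) variant records."""
        variants = list(variants)
        if not variants:
            raise ValueError("cannot build a mutation matrix from zero variants")
        for v in variants:
            if v.sample_id not in labels:
                raise ValueError(f"variant sample {v.sample_id!r} absent from labels")
        samples = labels.samples
        mutations = sorted({v.key for v in variants})
        row = {s: i for i, s in enumerate(samples)}
        col = {m: j for j, m in enumerate(mutations)}
        values = np.zeros((len(samples), len(mutations)), dtype=np.int8)
        for v in variants:
            values[row[v.sample_id], col[v.key]] = 1
        return cls(samples, mutations, values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def restrict(
        self,
        samples: Sequence[str] | None = None,
        mutations: Sequence[MutationKey] | None = None,
    ) -> "MutationMatrix":
        """Submatrix on the given samples and/or mutation keys (order preserved)."""
        samples = list(samples) if samples is not None else self.samples
        mutations = list(mutations) if mutations is not None else self.mutations
        ri = [self.samples.index(s) for s in samples]
        ci = [self.mutations.index(m) for m in mutations]
        return MutationMatrix(samples, mutations, self.values[np.ix_(ri, ci)])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{g}:{p}" for g, p in self.mutations]
        return pd.DataFrame(self.values, index=self.samples, columns=cols)


def filter_somatic_variants(
    tumor: Sequence[VariantRecord],
    normal: Sequence[VariantRecord],
    af_threshold: float = 0.1,
) -> list[VariantRecord]:
    """Apply the four somatic exclusion filters; input order is preserved.

    Removes tumor variants that (1) occur in the same sample's matched normal,
    (2) have population allele frequency strictly greater than *af_threshold*,
    (3) are synonymous or unclassifiable SNVs, or (4) fall outside exons and
    splice sites. The filters commute, so application order is irrelevant.
    """
    tumor_samples = {v.sample_id for v in tumor}
    unknown = {v.sample_id for v in normal} - tumor_samples
    if unknown:
        raise ValueError(
            f"matched-normal variants reference unknown samples: {sorted(unknown)}"
        )
    germline = {(v.sample_id, v.gene, v.protein_change) for v in normal}
    kept = []
    for v in tumor:
        if (v.sample_id, v.gene, v.protein_change) in germline:
            continue
        if v.population_af is not None and v.population_af > af_threshold:
            continue
        if v.variant_class in _EXCLUDED_CLASSES:
            continue
        if v.region not in _KEPT_REGIONS:
            continue
        kept.append(v)
    return kept


def build_mutation_matrix(
    variants: Iterable[VariantRecord], labels: CohortLabels
) -> MutationMatrix:
    """Binary incidence matrix of samples × mutation keys."""
    return MutationMatrix.from_variants(variants, labels)


def find_group_specific_mutations(
    mm: MutationMatrix, labels: CohortLabels, min_frac: float = 0.09
) -> list[MutationKey]:
    """Mutations in > ``min_frac`` of HRM samples and in zero LRM samples.

    Returned keys are sorted by descending HRM carrier frequency, then
    lexicographically.
    """
    hrm = [s for s in mm.samples if labels[s] == HRM]
    lrm = [s for s in mm.samples if labels[s] == LRM]
    if not hrm or not lrm:
        raise ValueError("both groups must be represented in the matrix")
    hrm_idx = [mm.samples.index(s) for s in hrm]
    lrm_idx = [mm.samples.index(s) for s in lrm]
    hrm_counts = mm.values[hrm_idx].sum(axis=0)
    lrm_counts = mm.values[lrm_idx].sum(axis=0)
    n_hrm = len(hrm)
    selected = [
        (hrm_counts[j] / n_hrm, mm.mutations[j])
        for j in range(len(mm.mutations))
        if hrm_counts[j] / n_hrm > min_frac and lrm_counts[j] == 0
    ]
    selected.sort(key=lambda t: (-t[0], t[1]))
    return [key for _, key in selected]


@dataclass
class BurdenSummary:
    """Per-sample mutation counts with a one-sided Welch t comparison."""

    counts: dict[str, int]
    group_means: dict[str, float]
    t_statistic: float
    p_value: float
    alternative: str = "greater"
    degenerate: bool = field(default=False)


def summarize_burden(
    mm: MutationMatrix, labels: CohortLabels, alternative: str = "greater"
) -> BurdenSummary:
    """Per-sample burden and a one-sided Welch t-test of HRM vs LRM means.

    ``alternative="greater"`` tests whether the HRM group carries more
    mutations on average. Fully degenerate input (zero variance in both
    groups, equal means) is reported as t=0, p=0.5 and flagged.
    """
    counts = dict(zip(mm.samples, mm.row_sums().astype(int)))
    h = np.array([counts[s] for s in mm.samples if labels[s] == HRM], dtype=float)
    l = np.array([counts[s] for s in mm.samples if labels[s] == LRM], dtype=float)
    if len(h) < 2 or len(l) < 2:
        raise ValueError("need at least two samples per group")
    means = {HRM: float(h.mean()), LRM: float(l.mean())}
    if h.std() == 0 and l.std() == 0 and h.mean() == l.mean():
        logger.warning("burden test degenerate: zero variance and equal means")
        return BurdenSummary(counts, means, 0.0, 0.5, alternative, degenerate=True)
    t, p = stats.ttest_ind(h, l, equal_var=False, alternative=alternative)
    return BurdenSummary(counts, means, float(t), float(p), alternative)


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_table(
    labels: CohortLabels, metadata: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Per-group counts and percentages for categorical patient attributes.

    *metadata* maps attribute name → {sample → level}. Samples missing an
    attribute are counted under ``"unknown"``. Percentages are computed
    against the group size and rounded half-up to one decimal, matching the
    usual clinical-table convention.
    """
    rows = []
    group_sizes = {g: len(labels.group(g)) for g in (HRM, LRM)}
    for attribute in metadata:
        values = metadata[attribute]
        for group in (HRM, LRM):
            members = labels.group(group)
            tally: dict[str, int] = {}
            for s in members:
                level = values.get(s, "unknown")
                tally[level] = tally.get(level, 0) + 1
            for level in sorted(tally):
                count = tally[level]
                rows.append(
                    {
                        "characteristic": attribute,
                        "level": level,
                        "group": group,
                        "count": count,
                        "percent": _round_half_up(100.0 * count / group_sizes[group]),
                    }
                )
    return pd.DataFrame(rows, columns=["characteristic", "level", "group", "count", "percent"])


def cohort_table_from_counts(
    counts: Mapping[str, Mapping[str, Mapping[str, int]]],
    group_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Same table as :func:`cohort_table`, from pre-tabulated counts.

    *counts* maps attribute → level → {group → count}; useful when only the
    aggregate table of a cohort is available rather than per-sample metadata.
    """
    rows = []
    for attribute, levels in counts.items():
        for level, per_group in levels.items():
            for group, count in per_group.items():
                rows.append(
                    {
                        "characteristic": attribute,
                        "level": level,
                        "group": group,
                        "count": count,
                        "percent": _round_half_up(100.0 * count / group_sizes[group]),
                    }
                )
    return pd.DataFrame(rows, columns=["characteristic", "level", "group", "count", "percent"])
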