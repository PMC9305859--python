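"""Panel tumor mutational burden and exposure-group statistics.

TMB is the number of somatic non-synonymous variants (missense, nonsense,
frameshift, splice-site) in the target region divided by the target size
in megabases.  Samples are split at the cohort median into low / high TMB
groups (values equal to the median go to low — a deterministic rule the
output metadata records).  Group comparisons follow the study's scheme:
Wilcoxon rank-sum (Mann-Whitney U) for continuous TMB contrasts, Fisher's
exact test for categorical contingency layouts, with Shapiro-Wilk used
only to annotate normality — the comparisons themselves are always
nonparametric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import DELETERIOUS, CohortClassification
from .landscape import fisher_exact_2x2
from .model import NONSYNONYMOUS, Cohort, Exposure, Onset

#: combined sample size at or below which the rank-sum p is exact
EXACT_RANKSUM_MAX_N = 12


@dataclass
class TMBProfile:
    """Per-sample burden plus the cohort median split."""

    table: pd.DataFrame  # sample_id, nonsyn_count, tmb, tmb_group
    median: float
    target_mb: float

    def tmb_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        sub = self.table.set_index("sample_id").loc[list(sample_ids)]
        return sub["tmb"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compute_tmb(cohort: Cohort) -> TMBProfile:
    """TMB for every sample in the cohort passed in (the analysis scope);
    samples without variants count zero."""
    target_mb = cohort.panel.target_mb
    if target_mb <= 0:
        raise ValueError("panel target size must be positive")
    counts = {s: 0 for s in cohort.samples}
    for v in cohort.variants:
        if v.consequence in NONSYNONYMOUS:
            counts[v.sample_id] += 1
    samples = cohort.samples
    tmb = {s: counts[s] / target_mb for s in samples}
    median = float(np.median([tmb[s] for s in samples])) if samples else 0.0
    table = pd.DataFrame(
        {
            "sample_id": samples,
            "nonsyn_count": [counts[s] for s in samples],
            "tmb": [tmb[s] for s in samples],
            "tmb_group": ["low" if tmb[s] <= median else "high" for s in samples],
        }
    )
    return TMBProfile(table=table, median=median, target_mb=target_mb)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U / Wilcoxon rank-sum test.

    Exact p by enumeration when the combined sample size is at most 12
    and the pooled data are tie-free; otherwise the normal approximation
    with tie correction.  The U statistic is reported for the first
    sample.  Identical pooled values give p = 1 (no evidence of shift).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact" if (len(pooled) <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p; annotation only, never drives test choice."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if len(values) > 5000:
        raise ValueError("Shapiro-Wilk supported up to n = 5000")
    w, p = stats.shapiro(values)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# group comparisons

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    scope: str  # 'all', 'exposed', or 'unexposed'
    group_labels: tuple[str, str]
    kind: str  # 'rank_sum' | 'fisher_exact'
    statistic: float
    p: float
    n1: int
    n2: int
    table: Optional[tuple[tuple[int, int], tuple[int, int]]] = None


@dataclass
class AssociationReport:
    comparisons: list[GroupComparison] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def get(self, variable: str, scope: str = "all") -> GroupComparison:
        for c in self.comparisons:
            if c.variable == variable and c.scope == scope:
                return c
        raise KeyError((variable, scope))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "variable": c.variable,
                "scope": c.scope,
                "groups": "|".join(c.group_labels),
                "kind": c.kind,
                "n1": c.n1,
                "n2": c.n2,
                "statistic": c.statistic,
                "p": c.p,
            }
            for c in self.comparisons
        ]
        pd.DataFrame(
            rows,
            columns=["variable", "scope", "groups", "kind", "n1", "n2", "statistic", "p"],
        ).to_csv(path, sep="\t", index=False)


def _tmb_contrast(
    report: AssociationReport,
    profile: TMBProfile,
    variable: str,
    scope: str,
    group1: list[str],
    group2: list[str],
    labels: tuple[str, str],
) -> None:
    if not group1 or not group2:
        report.skipped.append(
            f"{variable} [{scope}]: empty group ({labels[0]} n={len(group1)}, "
            f"{labels[1]} n={len(group2)})"
        )
        return
    u, p = rank_sum_test(profile.tmb_of(group1), profile.tmb_of(group2))
    report.comparisons.append(
        GroupComparison(
            variable=variable,
            scope=scope,
            group_labels=labels,
            kind="rank_sum",
            statistic=u,
            p=p,
            n1=len(group1),
            n2=len(group2),
        )
    )


#: Table-1 style binary covariates: name -> accessor on ClinicalRecord
_BINARY_COVARIATES = {
    "grade_iii": lambda c: c.grade_iii,
    "er_negative": lambda c: None if c.er is None else not c.er,
    "pr_negative": lambda c: None if c.pr is None else not c.pr,
    "her2_positive": lambda c: c.her2,
    "nodal_metastasis": lambda c: c.nodal,
    "distant_metastasis": lambda c: c.metastasis,
    "premenopause": lambda c: c.premenopause,
    "chemoresistance": lambda c: c.chemoresistance,
    "relapse": lambda c: c.relapse,
    "deceased": lambda c: c.deceased,
}


def clinical_associations(
    profile: TMBProfile,
    cohort: Cohort,
    classification: Optional[CohortClassification] = None,
) -> AssociationReport:
    """The study-style battery of group comparisons.

    Continuous TMB contrasts (rank-sum): exposure arms; within each arm,
    early vs late onset, per-gene mutation carriers vs wild-type, and —
    when a classification is supplied — deleterious (pathogenic or likely
    pathogenic) variant carriers vs non-carriers.  Categorical Table-1
    style covariates are compared exposed vs unexposed with Fisher's
    exact test on 2x2 layouts.  Strata with an empty group are skipped
    with the reason recorded.
    """
    report = AssociationReport()
    clin = cohort.clinical
    exposed = cohort.arm(Exposure.EXPOSED)
    unexposed = cohort.arm(Exposure.UNEXPOSED)

    _tmb_contrast(
        report, profile, "tmb_by_exposure", "all", exposed, unexposed,
        ("exposed", "unexposed"),
    )

    gene_carriers: dict[str, set[str]] = {g: set() for g in cohort.panel.genes}
    for v in cohort.variants:
        gene_carriers[v.gene].add(v.sample_id)

    deleterious_samples: Optional[set[str]] = None
    if classification is not None:
        deleterious_samples = {
            v.sample_id
            for v, cls in classification.records
            if cls.verdict in DELETERIOUS
        }

    for scope, arm_samples in (("exposed", exposed), ("unexposed", unexposed)):
        early = [s for s in arm_samples if clin[s].onset is Onset.EARLY]
        late = [s for s in arm_samples if clin[s].onset is Onset.LATE]
        _tmb_contrast(
            report, profile, "tmb_by_onset", scope, early, late, ("early", "late")
        )
        for gene in cohort.panel.genes:
            mut = [s for s in arm_samples if s in gene_carriers[gene]]
            wt = [s for s in arm_samples if s not in gene_carriers[gene]]
            _tmb_contrast(
                report, profile, f"tmb_by_{gene}_status", scope, mut, wt,
                ("mutated", "wild_type"),
            )
        if deleterious_samples is not None:
            carrier = [s for s in arm_samples if s in deleterious_samples]
            noncarrier = [s for s in arm_samples if s not in deleterious_samples]
            _tmb_contrast(
                report, profile, "tmb_by_deleterious", scope, carrier, noncarrier,
                ("deleterious", "none"),
            )

    if deleterious_samples is not None:
        carrier = [s for s in cohort.samples if s in deleterious_samples]
        noncarrier = [s for s in cohort.samples if s not in deleterious_samples]
        _tmb_contrast(
            report, profile, "tmb_by_deleterious", "all", carrier, noncarrier,
            ("deleterious", "none"),
        )

    # Table-1 style categorical covariates, exposed vs unexposed
    for name, accessor in _BINARY_COVARIATES.items():
        a = sum(1 for s in exposed if accessor(clin[s]) is True)
        b = sum(1 for s in exposed if accessor(clin[s]) is False)
        c = sum(1 for s in unexposed if accessor(clin[s]) is True)
        d = sum(1 for s in unexposed if accessor(clin[s]) is False)
        if (a + b) == 0 or (c + d) == 0:
            report.skipped.append(f"{name} [arms]: empty arm after missing-data drop")
            continue
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        report.comparisons.append(
            GroupComparison(
                variable=name,
                scope="all",
                group_labels=("exposed", "unexposed"),
                kind="fisher_exact",
                statistic=odds,
                p=p,
                n1=a + b,
                n2=c + d,
                table=((a, b), (c, d)),
            )
        )
    return report
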