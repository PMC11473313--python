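"""Case-control fusion association: the model / results pair.

`FusionAssociationModel` is built from per-run fusion calls plus a
cohort design (and optionally a gene annotation, which lets every
fusion be classified as readthrough/EFG or genomic/HFG candidate).
`fit()` collapses runs to patients, filters to recurrent fusions
(>= min_count distinct positive patients in either cohort), applies the
pooled two-proportion Z-test at the configured alpha to each surviving
fusion, and returns a `FusionAssociationResults` carrying the full
per-fusion table, per-category summaries, burden and presence-matrix
views, and the genetic-vs-environmental contribution split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .annotation import Annotation, read_annotation
from .cohort import (
    CASE,
    CONTROL,
    CohortDesign,
    DEFAULT_MIN_COUNT,
    Presence,
    burden_per_sample,
    collapse_runs_to_patients,
    filter_recurrent,
    presence_matrix,
    recurrence_table,
)
from .fusions import (
    DEFAULT_GAP_THRESHOLD,
    FusionJunction,
    classify_fusion,
)
from .stats import (
    contribution_split,
    critical_z,
    fold_enrichment,
    two_proportion_ztest,
)

#: Column order of the per-fusion association table.
TABLE_COLUMNS = [
    "fusion_id",
    "five_prime_gene",
    "three_prime_gene",
    "category",
    "mechanism",
    "gap_bp",
    "case_count",
    "case_freq",
    "control_count",
    "control_freq",
    "fold",
    "z_statistic",
    "p_value",
    "direction",
    "significant",
]


@dataclass(frozen=True)
class AssociationResult:
    """One fusion's association record (a row of the results table)."""

    fusion_id: str
    category: Optional[str]
    case_count: int
    case_freq: float
    control_count: int
    control_freq: float
    z_statistic: float
    p_value: float
    fold: float
    direction: str
    significant: bool


class FusionAssociationModel:
    """Two-cohort recurrence comparison of fusion transcripts.

    Parameters
    ----------
    calls : DataFrame
        Per-run fusion calls; requires ``run_id`` and ``fusion_id``
        columns, and uses ``five_prime_gene`` / ``three_prime_gene``
        (plus optional breakpoint columns) for classification when an
        annotation is supplied.
    design : CohortDesign
        Run-to-patient mapping and case/control assignment.
    annotation : mapping gene_id -> GeneModel, optional
        Enables EFG/GENOMIC classification; without it every fusion's
        category is reported as missing and the summary is not split.
    alpha : float
        Two-sided significance level for the Z-test (default 0.01,
        critical value 2.576).
    min_count : int
        Patient-recurrence filter: a fusion is tested iff at least this
        many distinct patients are positive in at least one cohort.
    gap_threshold : int
        Intergenic-gap bound (bp) for the readthrough/EFG rule.
    zero_pseudocount : int
        Control-count substitute when computing fold for fusions absent
        from controls.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        design: CohortDesign,
        annotation: Optional[Annotation] = None,
        *,
        alpha: float = 0.01,
        min_count: int = DEFAULT_MIN_COUNT,
        gap_threshold: int = DEFAULT_GAP_THRESHOLD,
        zero_pseudocount: int = 1,
    ) -> None:
        if design.n_case == 0 or design.n_control == 0:
            raise _cohort.DesignError(
                f"both cohorts must be non-empty (n_case={design.n_case}, "
                f"n_control={design.n_control})"
            )
        self.calls = calls
        self.design = design
        self.annotation = annotation
        self.alpha = alpha
        self.min_count = min_count
        self.gap_threshold = gap_threshold
        self.zero_pseudocount = zero_pseudocount

    @classmethod
    def from_files(
        cls,
        calls_path,
        design_path,
        annotation_path=None,
        **kwargs,
    ) -> "FusionAssociationModel":
        """Construct from a calls TSV, a design TSV and optional GTF/BED."""
        from .io import read_cohort_design, read_fusion_calls

        calls = read_fusion_calls(calls_path)
        design = read_cohort_design(design_path)
        annotation = read_annotation(annotation_path) if annotation_path else None
        return cls(calls, design, annotation, **kwargs)

    # -- classification ------------------------------------------------

    def _classify_all(self) -> pd.DataFrame:
        """One row per distinct fusion_id with partner genes and class."""
        cols = ["fusion_id"]
        has_genes = {"five_prime_gene", "three_prime_gene"} <= set(self.calls.columns)
        if has_genes:
            cols += ["five_prime_gene", "three_prime_gene"]
        bp_cols = [
            c
            for c in (
                "five_prime_chrom",
                "five_prime_pos",
                "three_prime_chrom",
                "three_prime_pos",
            )
            if c in self.calls.columns
        ]
        uniq = self.calls[cols + bp_cols].drop_duplicates("fusion_id").copy()
        categories, mechanisms, gaps = [], [], []
        for row in uniq.itertuples(index=False):
            if self.annotation is None or not has_genes:
                categories.append(None)
                mechanisms.append(None)
                gaps.append(None)
                continue
            bp5 = (
                (str(row.five_prime_chrom), int(row.five_prime_pos))
                if len(bp_cols) == 4
                else ("?", 0)
            )
            bp3 = (
                (str(row.three_prime_chrom), int(row.three_prime_pos))
                if len(bp_cols) == 4
                else ("?", 1)
            )
            j = FusionJunction(
                five_prime_gene=str(row.five_prime_gene),
                three_prime_gene=str(row.three_prime_gene),
                five_prime_breakpoint=bp5,
                three_prime_breakpoint=bp3,
            )
            fc = classify_fusion(j, self.annotation, self.gap_threshold)
            categories.append(fc.category.value)
            mechanisms.append(fc.mechanism.value)
            gaps.append(fc.gap_bp)
        uniq["category"] = categories
        uniq["mechanism"] = mechanisms
        uniq["gap_bp"] = gaps
        if not has_genes:
            uniq["five_prime_gene"] = None
            uniq["three_prime_gene"] = None
        return uniq.set_index("fusion_id")

    # -- fitting -------------------------------------------------------

    def fit(self) -> "FusionAssociationResults":
        """Run the collapse / filter / test pipeline and return results."""
        presence = collapse_runs_to_patients(self.calls, self.design)
        recurrence = recurrence_table(presence, self.design)
        keep_case = filter_recurrent(recurrence, CASE, self.min_count)
        keep_control = filter_recurrent(recurrence, CONTROL, self.min_count)
        tested = sorted(set(keep_case) | set(keep_control))

        info = self._classify_all()
        wide = recurrence.pivot(
            index="fusion_id", columns="cohort", values="positive_patients"
        )
        n1, n2 = self.design.n_case, self.design.n_control
        zcrit = critical_z(self.alpha)

        rows = []
        for f in tested:
            x1 = int(wide.loc[f, CASE]) if CASE in wide.columns else 0
            x2 = int(wide.loc[f, CONTROL]) if CONTROL in wide.columns else 0
            z, p = two_proportion_ztest(x1, n1, x2, n2)
            meta = info.loc[f] if f in info.index else None
            rows.append(
                {
                    "fusion_id": f,
                    "five_prime_gene": None if meta is None else meta["five_prime_gene"],
                    "three_prime_gene": None if meta is None else meta["three_prime_gene"],
                    "category": None if meta is None else meta["category"],
                    "mechanism": None if meta is None else meta["mechanism"],
                    "gap_bp": None if meta is None else meta["gap_bp"],
                    "case_count": x1,
                    "case_freq": x1 / n1,
                    "control_count": x2,
                    "control_freq": x2 / n2,
                    "fold": fold_enrichment(x1, n1, x2, n2, self.zero_pseudocount),
                    "z_statistic": z,
                    "p_value": p,
                    "direction": "positive" if x1 / n1 > x2 / n2 else "negative",
                    "significant": abs(z) >= zcrit,
                }
            )
        table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
        table = table.sort_values(
            ["case_count", "fusion_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        return FusionAssociationResults(
            model=self,
            table=table,
            presence=presence,
            recurrence=recurrence,
            critical_value=zcrit,
        )


@dataclass
class FusionAssociationResults:
    """Fitted association results.

    Attributes
    ----------
    table : DataFrame
        One row per tested fusion transcript with counts, exact
        frequencies, fold, Z statistic, two-sided p-value, direction
        and significance (see ``TABLE_COLUMNS``).
    presence : dict
        Per-patient presence sets (patient ID -> fusion IDs), the
        collapsed view all counts derive from.
    recurrence : DataFrame
        The unfiltered per-(fusion, cohort) recurrence table.
    critical_value : float
        |z| threshold used for the significance calls.
    """

    model: FusionAssociationModel
    table: pd.DataFrame
    presence: Presence
    recurrence: pd.DataFrame
    critical_value: float

    # -- views ---------------------------------------------------------

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def category_table(self, category: str) -> pd.DataFrame:
        return self.table[self.table["category"] == category]

    def class_of(self) -> dict[str, Optional[str]]:
        return dict(zip(self.table["fusion_id"], self.table["category"]))

    def fusion_gene_count(self, subset: Optional[pd.DataFrame] = None) -> int:
        """Distinct gene pairs among (a subset of) the tested transcripts."""
        t = self.table if subset is None else subset
        pairs = t[["five_prime_gene", "three_prime_gene"]].dropna()
        return len(pairs.drop_duplicates())

    def burden(self, cohort: Optional[str] = None, class_filter: Optional[str] = None):
        """Per-patient distinct-transcript counts and (min, max, mean)."""
        return burden_per_sample(
            self.presence,
            self.model.design,
            cohort=cohort,
            class_of=self.class_of() if class_filter else None,
            class_filter=class_filter,
        )

    def presence_matrix(
        self,
        cohort: Optional[str] = None,
        fusion_ids=None,
        category: Optional[str] = None,
    ) -> pd.DataFrame:
        """Binary patients x fusions matrix over the tested fusions."""
        if fusion_ids is None:
            t = self.table if category is None else self.category_table(category)
            fusion_ids = t["fusion_id"].tolist()
        return presence_matrix(self.presence, self.model.design, fusion_ids, cohort)

    # -- category summaries and the contribution split -----------------

    def mean_frequency_fold(self, category: Optional[str] = None) -> float:
        """Case-mean over control-mean frequency of positive significant fusions.

        This is the per-class enrichment summary: average the case
        frequencies of the significantly positively associated fusions
        of the class, average their control frequencies, and take the
        ratio.  NaN when the class has no such fusions or a zero
        control mean.
        """
        t = self.significant
        t = t[t["direction"] == "positive"]
        if category is not None:
            t = t[t["category"] == category]
        if t.empty or t["control_freq"].mean() == 0:
            return float("nan")
        return float(t["case_freq"].mean() / t["control_freq"].mean())

    def contribution_split(self) -> tuple[float, float]:
        """(genetic %, environmental %) from the GENOMIC vs EFG fold ratios."""
        h = self.mean_frequency_fold("GENOMIC")
        e = self.mean_frequency_fold("EFG")
        if not (np.isfinite(h) and np.isfinite(e)):
            raise ValueError(
                "contribution split needs significant positive fusions of both classes"
            )
        return contribution_split(h, e)

    def summary(self) -> str:
        """Human-readable per-category summary of the fitted results."""
        m = self.model
        lines = [
            "Fusion case-control association",
            "===============================",
            f"cohorts: {m.design.n_case} case / {m.design.n_control} control patients",
            f"alpha = {m.alpha} (|z| >= {self.critical_value:.3f}), "
            f"recurrence filter >= {m.min_count} patients in either cohort",
            f"tested fusion transcripts: {len(self.table)}",
        ]
        categories = [c for c in ("GENOMIC", "EFG") if (self.table["category"] == c).any()]
        if not categories:
            categories = [None]
        for cat in categories:
            t = self.table if cat is None else self.category_table(cat)
            sig = t[t["significant"]]
            pos = sig[sig["direction"] == "positive"]
            neg = sig[sig["direction"] == "negative"]
            label = cat or "all"
            lines.append(f"-- {label} --")
            lines.append(
                f"  transcripts tested {len(t)}, significant {len(sig)} "
                f"(positive {len(pos)}, negative {len(neg)}); "
                f"fusion genes tested {self.fusion_gene_count(t)}, "
                f"significant {self.fusion_gene_count(sig)}"
            )
            if len(pos):
                lines.append(
                    "  positive assoc. case freq "
                    f"{100 * pos['case_freq'].min():.1f}%-"
                    f"{100 * pos['case_freq'].max():.1f}% "
                    f"(mean {100 * pos['case_freq'].mean():.1f}%), "
                    f"control mean {100 * pos['control_freq'].mean():.2f}%"
                )
                fold = self.mean_frequency_fold(cat)
                if np.isfinite(fold):
                    lines.append(f"  mean-frequency fold (case/control): {fold:.1f}")
        try:
            g, e = self.contribution_split()
            lines.append(
                f"contribution split: genetic {g:.1f}% / environmental {e:.1f}%"
            )
        except ValueError:
            pass
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<FusionAssociationResults: {len(self.table)} tested, "
            f"{int(self.table['significant'].sum())} significant>"
        )
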