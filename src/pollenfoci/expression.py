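"""RT-qPCR relative expression with two-reference normalization.

The quantification follows the usual ddCt scheme with two reference genes:
technical replicates are averaged to one Ct per (sample, gene); the
normalized dCt of a target is its Ct minus the arithmetic mean of the two
reference Cts in the same sample (equivalent, at equal efficiencies, to
dividing by the geometric mean of reference quantities); relative expression
of a replicate is

    E^-(dCt - mean dCt of matched-timepoint controls)

with amplification efficiency E = 2 by default.  Treated and control groups
at each timepoint are then compared with a normality-gated test: Shapiro–
Wilk on both groups, Welch's t when both pass, otherwise the two-sided
rank-sum (Mann–Whitney) form of the Wilcoxon test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image_io import CT_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class ExpressionResult:
    """Per (gene, timepoint) relative-expression estimates and tests.

    ``replicates`` has one row per biological replicate (both arms) with its
    relative-expression value; ``summary`` has one row per (gene, timepoint)
    with the treated mean, its standard error, the chosen test and p-value.
    """

    replicates: pd.DataFrame
    summary: pd.DataFrame
    reference_genes: tuple[str, str]
    efficiency: float


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {', '.join(missing)}")
    return table


def relative_expression(
    table: pd.DataFrame,
    reference_genes: Sequence[str] = ("GAPC1", "EIF1a4"),
    efficiency: float = 2.0,
    alpha: float = 0.05,
    paired: bool = False,
) -> ExpressionResult:
    """Compute timepoint-matched relative expression from a long Ct table.

    Every (timepoint, treatment, bio_rep) sample block must contain both
    reference genes, and every timepoint must have control samples; either
    violation raises.  Control replicates are normalized to their own group
    mean, so control relative expression averages ~1 on the log scale.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ref1, ref2 = reference_genes
    df = _validate(table).copy()

    # technical replicates -> one Ct per (sample, gene)
    ct = (
        df.groupby(["timepoint", "treatment", "bio_rep", "gene"], as_index=False)["ct"]
        .mean()
    )
    wide = ct.pivot_table(
        index=["timepoint", "treatment", "bio_rep"], columns="gene", values="ct"
    )
    for ref in (ref1, ref2):
        if ref not in wide.columns or wide[ref].isna().any():
            bad = wide.index[wide[ref].isna()].tolist() if ref in wide.columns else "all"
            raise ValueError(f"reference gene {ref!r} missing in sample block(s): {bad}")
    ref_ct = wide[[ref1, ref2]].mean(axis=1)
    targets = [g for g in wide.columns if g not in (ref1, ref2)]

    rep_rows = []
    sum_rows = []
    for gene in targets:
        dct = wide[gene] - ref_ct
        for tp in dct.index.get_level_values("timepoint").unique():
            block = dct.xs(tp, level="timepoint")
            if "control" not in block.index.get_level_values("treatment"):
                raise ValueError(f"no matched control samples at timepoint {tp!r}")
            ctrl_dct = block.xs("control", level="treatment").dropna()
            if ctrl_dct.empty:
                raise ValueError(f"no control dCt for gene {gene!r} at timepoint {tp!r}")
            calib = ctrl_dct.mean()
            arms: dict[str, list[float]] = {}
            for treatment in block.index.get_level_values("treatment").unique():
                vals = block.xs(treatment, level="treatment").dropna()
                rel = efficiency ** (-(vals - calib))
                arms[treatment] = rel.tolist()
                for bio, r in zip(vals.index, rel):
                    rep_rows.append(
                        {
                            "gene": gene,
                            "timepoint": tp,
                            "treatment": treatment,
                            "bio_rep": bio,
                            "relative_expression": float(r),
                        }
                    )
            treated = arms.get("treated", [])
            control = arms.get("control", [])
            test_name, p = (None, np.nan)
            if len(treated) >= 3 and len(control) >= 3:
                test_name, p = test_expression(treated, control, alpha=alpha, paired=paired)
            sum_rows.append(
                {
                    "gene": gene,
                    "timepoint": tp,
                    "n_treated": len(treated),
                    "n_control": len(control),
                    "mean_relative_expression": float(np.mean(treated)) if treated else np.nan,
                    "sem_relative_expression": float(sps.sem(treated)) if len(treated) > 1 else np.nan,
                    "test": test_name,
                    "p_value": p,
                }
            )
    return ExpressionResult(
        replicates=pd.DataFrame(rep_rows),
        summary=pd.DataFrame(sum_rows),
        reference_genes=(ref1, ref2),
        efficiency=efficiency,
    )


def test_expression(
    treated: Sequence[float],
    control: Sequence[float],
    alpha: float = 0.05,
    paired: bool = False,
) -> tuple[str, float]:
    """Normality-gated two-sided comparison of two replicate groups.

    Shapiro–Wilk at ``alpha`` on each group; both normal -> Welch's t-test
    (paired t when ``paired``); otherwise the Wilcoxon rank-sum
    (Mann–Whitney) test, or signed-rank when ``paired``.  Two identical
    zero-variance groups return p = 1 by convention.
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            logger.warning("identical zero-variance groups; p = 1 by convention")
            return ("degenerate", 1.0)
        # constant but different groups: maximal evidence of a shift
        return ("degenerate", 0.0)

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        return sps.shapiro(x).pvalue >= alpha

    if _normal(a) and _normal(b):
        if paired:
            if a.size != b.size:
                raise ValueError("paired test requires equal group sizes")
            res = sps.ttest_rel(a, b)
            return ("Student-t (paired)", float(res.pvalue))
        res = sps.ttest_ind(a, b, equal_var=False)
        return ("Student-t", float(res.pvalue))
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        res = sps.wilcoxon(a, b)
        return ("Wilcoxon (signed-rank)", float(res.pvalue))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ("Wilcoxon", float(res.pvalue))
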