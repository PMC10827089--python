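"""Small statistics behind the figure-level comparisons.

Unpaired t-tests (Student pooled or Welch), Fisher's exact 2x2 test
(two-sided by the "sum of tables no more probable than observed"
convention), Pfaffl efficiency-corrected relative qPCR quantification, and
per-group expression proportion tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .domains import ElementLabel
from .genome import RepeatElement

logger = logging.getLogger(__name__)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def unpaired_ttest(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    equal_variance: bool = True,
) -> TTestResult:
    """Two-sided unpaired t-test.

    ``equal_variance=True`` gives the Student (pooled-variance) test;
    otherwise Welch. Each sample needs n >= 2 and the pooled variance must
    be nonzero.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    for name, x in (("sample_a", a), ("sample_b", b)):
        if not np.all(np.isfinite(x)):
            raise ValueError(f"{name} contains non-finite values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical degenerate samples: no evidence of difference
            return TTestResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        which = "sample_a" if np.var(a, ddof=1) == 0 else "sample_b"
        raise ValueError(f"degenerate (zero) variance in {which}")
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    if equal_variance:
        df = float(len(a) + len(b) - 2)
    else:
        df = float(res.df)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on [[a, b], [c, d]].

    Returns (odds_ratio, two-sided p). p sums hypergeometric probabilities
    of all tables with the observed margins that are no more probable than
    the observed one. odds_ratio = ad/bc, with inf when bc == 0 and ad > 0
    and nan for the all-degenerate 0/0 case.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def pfaffl_relative_quantity(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected relative quantity: E_t^dCt_t / E_ref^dCt_ref.

    dCt is Ct(control) - Ct(treated); amplification efficiencies E must lie
    in (1, 2] (2 = perfect doubling per cycle). A ratio of 0.5 with equal
    efficiencies therefore means the target halved relative to the
    reference.
    """
    for name, e in (("e_target", e_target), ("e_ref", e_ref)):
        if not 1.0 < e <= 2.0:
            raise ValueError(f"{name} must be in (1, 2], got {e}")
    return float(e_target**dct_target / e_ref**dct_ref)


def group_proportions(
    labels: Sequence[ElementLabel],
    elements: Sequence[RepeatElement],
) -> pd.DataFrame:
    """Expression proportion per association class x completeness group.

    Groups are {CENPA_CEN, CENPA_nonCEN, nonCENPA} x {all, full_length,
    truncated}, plus the collapsed CENP-A (CEN + nonCEN) vs nonCENPA
    grouping. Reports n, n_expressed, proportion, and the mean/SD of
    per-copy read densities (reads per kb). Empty groups are omitted with a
    warning.
    """
    by_id = {el.element_id: el for el in elements}
    missing = [lab.element_id for lab in labels if lab.element_id not in by_id]
    if missing:
        raise ValueError(f"labels refer to unknown elements: {missing[:5]}")
    rows = []
    for lab in labels:
        el = by_id[lab.element_id]
        rows.append(
            {
                "element_id": lab.element_id,
                "association": lab.association,
                "completeness": el.completeness or "truncated",
                "expressed": lab.expressed,
                "density": lab.read_count / (el.length / 1000.0),
            }
        )
    df = pd.DataFrame(rows)

    out = []

    def _summ(sub: pd.DataFrame, association: str, completeness: str, collapsed: bool) -> None:
        if len(sub) == 0:
            warnings.warn(f"group {association} x {completeness} is empty; omitted", stacklevel=3)
            return
        out.append(
            {
                "association": association,
                "completeness": completeness,
                "collapsed": collapsed,
                "n": len(sub),
                "n_expressed": int(sub["expressed"].sum()),
                "proportion": float(sub["expressed"].mean()),
                "mean_density": float(sub["density"].mean()),
                "sd_density": float(sub["density"].std(ddof=1)) if len(sub) > 1 else 0.0,
            }
        )

    for assoc in ("CENPA_CEN", "CENPA_nonCEN", "nonCENPA"):
        sub_a = df[df["association"] == assoc]
        for comp in ("all", "full_length", "truncated"):
            sub = sub_a if comp == "all" else sub_a[sub_a["completeness"] == comp]
            _summ(sub, assoc, comp, collapsed=False)
    # collapsed CENP-A grouping
    cenpa = df[df["association"].isin(["CENPA_CEN", "CENPA_nonCEN"])]
    for comp in ("all", "full_length", "truncated"):
        sub = cenpa if comp == "all" else cenpa[cenpa["completeness"] == comp]
        _summ(sub, "CENPA", comp, collapsed=True)
        sub_n = df[df["association"] == "nonCENPA"]
        sub_n = sub_n if comp == "all" else sub_n[sub_n["completeness"] == comp]
        # nonCENPA rows already emitted uncollapsed; keep table tidy
    return pd.DataFrame(out)
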