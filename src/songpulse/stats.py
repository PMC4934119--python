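"""Mixed-effects comparison of pulse deviation between groups.

FRMSD grows with the number of notes in a chunk (more onsets, more chances
to deviate), so group comparisons — real vs surrogate song, or directed vs
undirected song — use a linear mixed model with the group as fixed effect
and a random intercept per distinct note count. Significance comes from a
likelihood-ratio test of the full model against the model without the
group term, both fitted by maximum likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ComparisonRecord",
    "LmmResult",
    "SummaryRow",
    "lmm_group_test",
    "pairs_to_long",
    "summarize_comparisons",
    "summary_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonRecord:
    """One FRMSD observation: chunk, repetition, group label, note count."""

    chunk_ref: tuple[str, int]
    rep: int
    group: str
    frmsd: float
    n_notes: int


@dataclass(frozen=True)
class LmmResult:
    """Likelihood-ratio test of the group fixed effect."""

    chi_squared: float
    df: int
    p_value: float
    direction: str  # group label with the lower fitted mean FRMSD
    converged: bool
    coef: float


def _records_frame(records: Sequence[ComparisonRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "group": [r.group for r in records],
                "frmsd": [r.frmsd for r in records],
                "n_notes": [r.n_notes for r in records],
            }
        )
    return df


def lmm_group_test(
    records: Sequence[ComparisonRecord] | pd.DataFrame, alpha: float = 0.05
) -> LmmResult:
    """LMM of FRMSD on group with a random intercept per note count.

    Both the full model (``frmsd ~ group``) and the reduced model
    (``frmsd ~ 1``), each with the ``n_notes`` random intercept, are fitted
    by maximum likelihood; the p-value is the chi-squared tail of twice the
    log-likelihood difference on 1 degree of freedom. ``direction`` names
    the group with the lower fitted mean.
    """
    df = _records_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if df["n_notes"].nunique() < 2:
        raise ValueError(
            "random intercept per note count is degenerate: all records share "
            "one n_notes value"
        )
    df = df.copy()
    df["n_notes"] = df["n_notes"].astype("category")
    means = df.groupby("group", observed=True)["frmsd"].mean()
    mean_diff = float(means[groups[1]] - means[groups[0]])
    if float(df["frmsd"].var()) == 0.0:
        # all observations identical: no evidence in either direction
        return LmmResult(chi_squared=0.0, df=1, p_value=1.0, direction=groups[1],
                         converged=True, coef=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # a singular random-effects covariance (variance shrunk to zero) is
        # expected when note count explains little; the LRT remains valid
        warnings.filterwarnings("ignore", message="Random effects covariance")
        full = smf.mixedlm("frmsd ~ C(group)", df, groups=df["n_notes"]).fit(reml=False)
        reduced = smf.mixedlm("frmsd ~ 1", df, groups=df["n_notes"]).fit(reml=False)
    stat = 2.0 * (full.llf - reduced.llf)
    if not np.isfinite(stat):
        # degenerate but clear-cut: zero residual variance under the full
        # model (each group perfectly explained) drives its likelihood to
        # infinity; report the limit of the test
        direction = groups[0] if mean_diff > 0 else groups[1]
        return LmmResult(chi_squared=float("inf"), df=1, p_value=0.0,
                         direction=direction, converged=False, coef=mean_diff)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df=1))
    coef_name = [n for n in full.params.index if n.startswith("C(group)")][0]
    coef = float(full.params[coef_name])
    # treatment coding: coef > 0 means the second group sits higher
    direction = groups[0] if coef > 0 else groups[1]
    return LmmResult(
        chi_squared=float(stat),
        df=1,
        p_value=p,
        direction=direction,
        converged=bool(full.converged and reduced.converged),
        coef=coef,
    )


@dataclass(frozen=True)
class SummaryRow:
    """Per-bird, per-model summary over repetitions (percentages of reps)."""

    bird_id: str
    model: str
    pct_dev_bird_lt_model: float
    pct_sig_bird_lt_model: float
    pct_dev_model_lt_bird: float
    pct_sig_model_lt_bird: float
    n_reps: int
    n_ties: int


def pairs_to_long(pairs: pd.DataFrame) -> pd.DataFrame:
    """Reshape a paired comparison table to one row per (chunk, rep, group).

    ``pairs`` is the output of :func:`songpulse.nullmodels.run_comparison`
    with columns ``frmsd_real``/``frmsd_model``; the result has ``group``
    in {"real", "model"} and a single ``frmsd`` column.
    """
    real = pairs[["bird_id", "chunk_index", "rep", "n_notes", "frmsd_real"]].rename(
        columns={"frmsd_real": "frmsd"}
    )
    real["group"] = "real"
    model = pairs[["bird_id", "chunk_index", "rep", "n_notes", "frmsd_model"]].rename(
        columns={"frmsd_model": "frmsd"}
    )
    model["group"] = "model"
    return pd.concat([real, model], ignore_index=True)


def summarize_comparisons(
    pairs: pd.DataFrame, alpha: float = 0.05
) -> list[SummaryRow]:
    """Per-bird/model summary: in what share of repetitions did the real song
    fit the pulse better, and in what share significantly so.

    For every repetition one LMM (real vs surrogate, random intercept per
    note count) decides direction and significance; the summary reports the
    percentage of repetitions per direction and, within each direction, the
    percentage reaching ``alpha``. Repetitions with an exact mean tie (LMM
    coefficient exactly zero) count toward neither direction and are logged.
    """
    rows = []
    for (bird_id, model), sub in pairs.groupby(["bird_id", "model"], sort=True):
        n_reps = sub["rep"].nunique()
        bird_lt = sig_bird = model_lt = sig_model = ties = 0
        for _, rep_pairs in sub.groupby("rep"):
            long = pairs_to_long(rep_pairs)
            try:
                res = lmm_group_test(long, alpha=alpha)
            except ValueError:
                # single note-count level: fall back to the mean difference
                diff = (rep_pairs["frmsd_real"] - rep_pairs["frmsd_model"]).mean()
                if diff == 0:
                    ties += 1
                    continue
                if diff < 0:
                    bird_lt += 1
                else:
                    model_lt += 1
                continue
            if res.coef == 0:
                ties += 1
                continue
            if res.direction == "real":
                bird_lt += 1
                sig_bird += res.p_value < alpha
            else:
                model_lt += 1
                sig_model += res.p_value < alpha
        if ties:
            logger.info(
                "bird %s model %s: %d repetition(s) tied exactly; counted to "
                "neither direction",
                bird_id,
                model,
                ties,
            )
        rows.append(
            SummaryRow(
                bird_id=str(bird_id),
                model=str(model),
                pct_dev_bird_lt_model=100.0 * bird_lt / n_reps,
                pct_sig_bird_lt_model=100.0 * sig_bird / n_reps,
                pct_dev_model_lt_bird=100.0 * model_lt / n_reps,
                pct_sig_model_lt_bird=100.0 * sig_model / n_reps,
                n_reps=n_reps,
                n_ties=ties,
            )
        )
    return rows


def summary_table(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Summary rows as a table mirroring the standard column layout."""
    return pd.DataFrame(
        [
            {
                "bird_id": r.bird_id,
                "model": r.model,
                "pct_dev_bird_lt_model": r.pct_dev_bird_lt_model,
                "pct_sig_bird_lt_model": r.pct_sig_bird_lt_model,
                "pct_dev_model_lt_bird": r.pct_dev_model_lt_bird,
                "pct_sig_model_lt_bird": r.pct_sig_model_lt_bird,
                "n_reps": r.n_reps,
                "n_ties": r.n_ties,
            }
            for r in rows
        ]
    )
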