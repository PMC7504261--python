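"""Validation statistics: ICC, intersystem CMC, relative error, risk-level
confusion matrices, and absolute-difference summaries.

These are the statistics used to validate an automated scoring system
against expert raters or a reference system:

* **ICC** — intraclass correlation, default two-way random effects /
  absolute agreement / single measures (ICC(2,1)), with an F-based 95% CI.
  Interpretation bands: < 0.4 poor; 0.4-0.6 fair; 0.6-0.75 good;
  >= 0.75 excellent reliability.
* **Intersystem CMC** — coefficient of multiple correlation between
  time-aligned waveforms from two (or more) measurement systems, the
  between-protocol formulation from the gait literature: the complement of
  the ratio of scatter about per-frame means to scatter about the grand
  mean, square-rooted.  Bands: > 0.9 strong; 0.5-0.9 moderate; 0.25-0.5
  weak; <= 0.25 poor association.
* **Relative error %** — 100 x RMSE(predicted, reference) / max(reference).
* **Risk confusion** — K x K counts of system-assigned vs reference ordinal
  risk levels; accuracy = trace / total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UndefinedStatisticError

ICC_BANDS = (
    (0.4, "poor reliability"),
    (0.6, "fair reliability"),
    (0.75, "good reliability"),
    (np.inf, "excellent reliability"),
)

CMC_BANDS = (
    (0.25, "poor association"),
    (0.5, "weak association"),
    (0.9, "moderate association"),
    (np.inf, "strong association"),
)


def interpret_icc(value: float) -> str:
    """Reliability band for an ICC value per the standard guideline."""
    for upper, band in ICC_BANDS:
        if value < upper:
            return band
    raise AssertionError  # pragma: no cover


def interpret_cmc(value: float) -> str:
    """Association band for a CMC value per the standard guideline."""
    for upper, band in CMC_BANDS:
        if value <= upper or upper is np.inf:
            return band
    raise AssertionError  # pragma: no cover


@dataclass
class IccResult:
    value: float
    ci95: tuple[float, float]
    band: str
    model: str


def icc(
    ratings: np.ndarray | pd.DataFrame,
    model: str = "two-way-random-absolute-single",
) -> IccResult:
    """ICC of a subjects x raters matrix.

    The default (and currently only) model is two-way random effects,
    absolute agreement, single measures — ICC(2,1) — computed from the
    two-way ANOVA variance components, with the standard F-distribution 95%
    CI.  Raises :class:`UndefinedStatisticError` when the matrix has zero
    total variance.
    """
    if model != "two-way-random-absolute-single":
        raise ValueError(f"unsupported ICC model {model!r}")
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise EmptyInputError("ratings must be a matrix with >= 2 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise EmptyInputError("ratings matrix must have no missing cells")
    if np.ptp(m) == 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")

    n, k = m.shape
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": m.ravel(),
        }
    )
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
    # pingouin labels the two-way random / absolute / single-measures row
    # "ICC2" in some releases and "ICC(A,1)" in others
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    value = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci = tuple(float(x) for x in row[ci_col])
    return IccResult(value=value, ci95=ci, band=interpret_icc(value), model=model)


@dataclass
class CmcResult:
    value: float
    band: str
    clipped: bool


def intersystem_cmc(waveforms: np.ndarray | pd.DataFrame) -> CmcResult:
    """Intersystem CMC of a frames x systems waveform matrix.

    CMC^2 = 1 - [ sum_fs (y_fs - ybar_f)^2 / (F (S-1)) ]
              / [ sum_fs (y_fs - ybar)^2   / (F S - 1) ]

    with ybar_f the per-frame mean over systems and ybar the grand mean.
    A negative radicand (waveforms less similar than chance) is clipped to
    0 with a warning.  Raises :class:`UndefinedStatisticError` when no
    system shows any frame-to-frame variation.
    """
    y = np.asarray(waveforms, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise EmptyInputError("waveforms must be frames x systems with >= 2 of each")
    f, s = y.shape
    frame_means = y.mean(axis=1, keepdims=True)
    grand = y.mean()
    denom = np.sum((y - grand) ** 2) / (f * s - 1)
    if denom == 0 or np.all(np.ptp(y, axis=0) == 0):
        raise UndefinedStatisticError(
            "CMC undefined: zero frame-to-frame variance in all systems"
        )
    num = np.sum((y - frame_means) ** 2) / (f * (s - 1))
    radicand = 1.0 - num / denom
    clipped = radicand < 0
    if clipped:
        warnings.warn("CMC radicand negative; clipping coefficient to 0", stacklevel=2)
    value = float(np.sqrt(max(0.0, radicand)))
    value = min(value, 1.0)
    return CmcResult(value=value, band=interpret_cmc(value), clipped=clipped)


def relative_error_pct(predicted, reference) -> float:
    """100 x RMSE(predicted, reference) / max(reference)."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise EmptyInputError("predicted and reference must be equal-length, non-empty")
    ref_max = r.max()
    if ref_max <= 0:
        raise UndefinedStatisticError("relative error undefined: max(reference) <= 0")
    rmse = float(np.sqrt(np.mean((p - r) ** 2)))
    return 100.0 * rmse / float(ref_max)


@dataclass
class ConfusionMatrix:
    """System-assigned (rows) vs reference (columns) ordinal risk levels."""

    counts: pd.DataFrame  # rows/cols labelled by ordered categories

    def __post_init__(self):
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("confusion counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def accuracy(self) -> float:
        """trace / total, in [0, 1]."""
        return float(np.trace(self.counts.to_numpy()) / self.total)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    @classmethod
    def from_counts(cls, counts, categories) -> "ConfusionMatrix":
        df = pd.DataFrame(
            np.asarray(counts, dtype=int), index=list(categories), columns=list(categories)
        )
        return cls(df)


def risk_confusion(
    system_levels, reference_levels, categories=None
) -> ConfusionMatrix:
    """Tally a confusion matrix from per-observation risk-level labels.

    ``categories`` fixes the (ordered) label set; by default it is the
    sorted union of observed labels.  Unknown labels raise ``ValueError``.
    """
    sys_l = list(system_levels)
    ref_l = list(reference_levels)
    if len(sys_l) != len(ref_l):
        raise EmptyInputError("system and reference label sequences differ in length")
    if not sys_l:
        raise EmptyInputError("no observations")
    if categories is None:
        categories = sorted(set(sys_l) | set(ref_l))
    cats = list(categories)
    unknown = (set(sys_l) | set(ref_l)) - set(cats)
    if unknown:
        raise ValueError(f"unknown risk-level labels: {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for a, b in zip(sys_l, ref_l):
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(pd.DataFrame(counts, index=cats, columns=cats))


@dataclass
class AbsoluteDifferenceSummary:
    mean: float
    sd: float
    interval95: tuple[float, float]


def absolute_difference_summary(system_scores, reference_scores) -> AbsoluteDifferenceSummary:
    """Mean +/- SD and the empirical central 95% interval of per-observation
    absolute differences between two score vectors."""
    a = np.asarray(system_scores, dtype=float)
    b = np.asarray(reference_scores, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise EmptyInputError("score vectors must be equal-length and non-empty")
    d = np.abs(a - b)
    return AbsoluteDifferenceSummary(
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        interval95=(float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975))),
    )
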