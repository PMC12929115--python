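"""Split-plot (mixed) ANOVA with sphericity diagnostics, built from scratch.

The design is the classic repeated-measures split plot: each unit (an eye rated
by one grader, by default) carries between-subject factor levels (diagnosis,
grader) and is measured once under every level of a within-subject factor
(imaging modality). The decomposition runs in two orthogonal strata:

* between stratum — ordinary two-way ANOVA on the per-unit means (scaled by the
  number of within levels k), with error = units within between-cells;
* within stratum — the within factor and its interactions with the between
  factors, fitted to the per-unit deviations from the unit mean, with error =
  within x units-within-cells.

Sums of squares are Type III via sum-to-zero (deviation) contrast coding and
full-versus-reduced model comparison, so unbalanced between-cells (the realistic
case: cohort sizes differ by diagnosis) are handled the way mainstream
statistics packages do; on balanced designs the result coincides with the
classical expected-mean-squares decomposition exactly.

Sphericity of the within covariance is assessed on the pooled within-cell
covariance S projected onto an orthonormal contrast basis C (C 1 = 0,
C C' = I), S_c = C S C':

* Mauchly's W = det(S_c) / (tr(S_c) / (k-1))^(k-1), with the chi-square
  approximation chi2 = -(n_e - (2d^2 + d + 2)/(6d)) * ln W on
  d(d+1)/2 - 1 degrees of freedom, where d = k - 1 and n_e is the
  between-stratum error df (the Box correction factor);
* Greenhouse-Geisser epsilon = (tr S_c)^2 / ((k-1) * tr(S_c^2)), bounded in
  [1/(k-1), 1]; within-stratum df are multiplied by epsilon before corrected
  p-values are computed.

Both are invariant to the choice of orthonormal contrast basis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GradeRecord, UnitDefinition
from .scoring import DEFAULT_SCHEME, ScoringScheme, accuracy_long

__all__ = [
    "LongDataset",
    "AnovaEffectRow",
    "SphericityResult",
    "PairwiseComparison",
    "AnovaResult",
    "fit_mixed_anova",
    "mauchly_test",
    "greenhouse_geisser_epsilon",
    "epsilon_from_contrast_covariance",
    "mauchly_w_from_contrast_covariance",
    "posthoc_pairwise",
    "partial_eta_squared",
]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LongDataset:
    """Long-format repeated-measures dataset.

    ``data`` has one row per (unit, within level) with the between-factor
    levels repeated on every row of a unit. ``between`` names one or two
    between-subject factor columns; ``within`` the repeated factor; ``response``
    the numeric outcome (accuracy percent in this package's pipeline).
    """

    data: pd.DataFrame
    unit: str = "unit"
    between: tuple[str, ...] = ("diagnosis", "grader_id")
    within: str = "modality"
    response: str = "accuracy"

    @classmethod
    def from_records(
        cls,
        records: Iterable[GradeRecord],
        scheme: ScoringScheme = DEFAULT_SCHEME,
        unit_definition: UnitDefinition = UnitDefinition.EYE_BY_GRADER,
    ) -> "LongDataset":
        """Score records and assemble the ANOVA long format.

        With ``EYE_BY_GRADER`` each (subject, eye, grader) triple is a unit;
        with ``SUBJECT_BY_GRADER`` fellow eyes of bilateral subjects are
        averaged per modality first, so the unit is (subject, grader).
        """
        df = accuracy_long(records, scheme)
        if unit_definition is UnitDefinition.EYE_BY_GRADER:
            df = df.copy()
            df["unit"] = df["subject_id"] + ":" + df["eye"] + ":" + df["grader_id"]
        else:
            df = (
                df.groupby(["subject_id", "diagnosis", "grader_id", "modality"], sort=False)[
                    "accuracy"
                ]
                .mean()
                .reset_index()
            )
            df["unit"] = df["subject_id"] + ":" + df["grader_id"]
        return cls(data=df)

    def within_levels(self) -> list:
        seen: dict = {}
        for v in self.data[self.within]:
            seen.setdefault(v, None)
        return list(seen)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaEffectRow:
    """One line of the ANOVA table.

    ``df_gg``/``error_df_gg``/``p_gg`` are populated only for within-stratum
    effects, holding the Greenhouse-Geisser corrected (non-integer) degrees of
    freedom and p-value. F and p are NaN when the stratum error mean square is
    zero (e.g. constant responses).
    """

    effect: str
    ss: float
    df: float
    ms: float
    f: float
    p: float
    partial_eta_sq: float
    stratum: str  # "between" | "within" | "error"
    df_gg: float = float("nan")
    error_df_gg: float = float("nan")
    p_gg: float = float("nan")


@dataclass(frozen=True)
class SphericityResult:
    """Mauchly's test and Greenhouse-Geisser epsilon for the within factor."""

    w: float
    chi2: float
    df: int
    p_value: float
    epsilon_gg: float
    k: int
    singular: bool = False


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: str
    level_b: str
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    reject: bool
    kind: str  # "paired" | "welch" | "pooled"


@dataclass(frozen=True)
class AnovaResult:
    """Full split-plot decomposition: effect rows plus sphericity diagnostics."""

    rows: tuple[AnovaEffectRow, ...]
    sphericity: SphericityResult | None
    n_units: int
    excluded_units: tuple[str, ...]
    alpha: float

    def __getitem__(self, effect: str) -> AnovaEffectRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    def table(self) -> pd.DataFrame:
        """ANOVA table as a DataFrame (SS, df, MS, F, p, partial eta squared)."""
        return pd.DataFrame(
            [
                {
                    "effect": r.effect,
                    "stratum": r.stratum,
                    "SS": r.ss,
                    "df": r.df,
                    "MS": r.ms,
                    "F": r.f,
                    "p": r.p,
                    "partial_eta_sq": r.partial_eta_sq,
                    "df_GG": r.df_gg,
                    "error_df_GG": r.error_df_gg,
                    "p_GG": r.p_gg,
                }
                for r in self.rows
            ]
        )


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------


def _sum_to_zero_coding(n_levels: int) -> np.ndarray:
    """(n_levels, n_levels - 1) deviation-coding matrix (last level = -1 row)."""
    c = np.eye(n_levels, n_levels - 1)
    c[-1, :] = -1.0
    return c


def _factor_codes(values: pd.Series) -> tuple[np.ndarray, list]:
    levels: dict = {}
    for v in values:
        levels.setdefault(v, None)
    levels = list(levels)
    index = {lvl: i for i, lvl in enumerate(levels)}
    return np.array([index[v] for v in values]), levels


def _interaction_columns(parts: Sequence[np.ndarray]) -> np.ndarray:
    """Row-wise Khatri-Rao product of coded factor columns."""
    out = parts[0]
    for nxt in parts[1:]:
        out = np.einsum("ij,ik->ijk", out, nxt).reshape(out.shape[0], -1)
    return out


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    if x.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Normalized Helmert contrasts: (k-1, k), rows orthonormal, orthogonal to 1."""
    c = np.zeros((k - 1, k))
    for j in range(1, k):
        c[j - 1, :j] = 1.0
        c[j - 1, j] = -j
        c[j - 1] /= np.linalg.norm(c[j - 1])
    return c


# ---------------------------------------------------------------------------
# pivoting and pooled covariance
# ---------------------------------------------------------------------------


def _pivot(data: LongDataset):
    """Wide response matrix plus per-unit between labels; excludes incomplete units."""
    df = data.data
    required = [data.unit, *data.between, data.within, data.response]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dataset lacks column(s) {missing}")
    dup = df.duplicated(subset=[data.unit, data.within])
    if dup.any():
        bad = df.loc[dup, data.unit].unique()[:5]
        raise ValueError(f"multiple responses for one (unit, within) pair, e.g. units {list(bad)}")

    within_levels = data.within_levels()
    k = len(within_levels)
    wide = df.pivot(index=data.unit, columns=data.within, values=data.response)
    wide = wide.reindex(columns=within_levels)
    complete = wide.notna().all(axis=1)
    excluded = tuple(str(u) for u in wide.index[~complete])
    wide = wide.loc[complete]
    if wide.empty:
        raise ValueError("no unit has a complete within-profile")

    labels = df.drop_duplicates(subset=data.unit).set_index(data.unit)[list(data.between)]
    consistency = df.groupby(data.unit)[list(data.between)].nunique()
    if (consistency > 1).any().any():
        raise ValueError("a unit carries more than one level of a between factor")
    labels = labels.loc[wide.index]
    return wide, labels, within_levels, excluded


def _pooled_contrast_covariance(
    y: np.ndarray, cell_ids: np.ndarray, basis: np.ndarray
) -> tuple[np.ndarray, int]:
    """Pooled within-cell covariance of y (N x k), projected onto the contrast basis.

    Returns (S_c, error_df) with error_df = N - number of cells.
    """
    n, k = y.shape
    resid = np.empty_like(y, dtype=float)
    cells = np.unique(cell_ids)
    for c in cells:
        mask = cell_ids == c
        resid[mask] = y[mask] - y[mask].mean(axis=0)
    n_e = n - len(cells)
    if n_e < 1:
        raise ValueError("not enough units to estimate the within covariance")
    s = resid.T @ resid / n_e
    return basis @ s @ basis.T, n_e


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------


def epsilon_from_contrast_covariance(s_c: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon = (tr S_c)^2 / ((k-1) tr(S_c^2)).

    Falls back to the lower bound 1/(k-1) when the contrast covariance is zero
    (constant data), where the ratio is undefined.
    """
    d = s_c.shape[0]
    tr = float(np.trace(s_c))
    tr_sq = float(np.trace(s_c @ s_c))
    if tr_sq <= 0.0:
        return 1.0 / d
    eps = tr * tr / (d * tr_sq)
    return float(min(1.0, max(1.0 / d, eps)))


def mauchly_w_from_contrast_covariance(s_c: np.ndarray) -> float:
    """Mauchly's W = det(S_c) / (tr(S_c)/(k-1))^(k-1), clipped to [0, 1]."""
    d = s_c.shape[0]
    tr = float(np.trace(s_c))
    if tr <= 0.0:
        return float("nan")
    det = float(np.linalg.det(s_c))
    w = det / (tr / d) ** d
    return float(min(1.0, max(0.0, w)))


def _sphericity_from_cov(s_c: np.ndarray, n_e: int, k: int) -> SphericityResult:
    d = k - 1
    eps = epsilon_from_contrast_covariance(s_c)
    if k == 2:
        # a single contrast variance is trivially spherical
        return SphericityResult(w=1.0, chi2=0.0, df=0, p_value=1.0, epsilon_gg=1.0, k=k)
    w = mauchly_w_from_contrast_covariance(s_c)
    singular = not np.isfinite(w) or w <= 0.0
    df = d * (d + 1) // 2 - 1
    if singular:
        return SphericityResult(
            w=0.0 if np.isfinite(w) else float("nan"),
            chi2=float("inf"),
            df=df,
            p_value=0.0,
            epsilon_gg=eps,
            k=k,
            singular=True,
        )
    # Box's chi-square approximation to the likelihood-ratio statistic
    box = (2.0 * d * d + d + 2.0) / (6.0 * d)
    chi2 = -(n_e - box) * np.log(w)
    p = float(stats.chi2.sf(chi2, df)) if chi2 >= 0 else 1.0
    return SphericityResult(w=w, chi2=float(chi2), df=df, p_value=p, epsilon_gg=eps, k=k)


def _prepare_covariance(data: LongDataset, basis: np.ndarray | None):
    wide, labels, within_levels, _ = _pivot(data)
    k = len(within_levels)
    if k < 2:
        raise ValueError("sphericity needs at least two within levels")
    if basis is None:
        basis = _orthonormal_contrasts(k)
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (k - 1, k):
        raise ValueError(f"contrast basis must be {(k - 1, k)}, got {basis.shape}")
    cell_ids = labels.astype(str).agg("|".join, axis=1).to_numpy()
    s_c, n_e = _pooled_contrast_covariance(wide.to_numpy(dtype=float), cell_ids, basis)
    return s_c, n_e, k


def mauchly_test(data: LongDataset, basis: np.ndarray | None = None) -> SphericityResult:
    """Mauchly's sphericity test on the pooled within-cell contrast covariance."""
    s_c, n_e, k = _prepare_covariance(data, basis)
    return _sphericity_from_cov(s_c, n_e, k)


def greenhouse_geisser_epsilon(data: LongDataset, basis: np.ndarray | None = None) -> float:
    """Greenhouse-Geisser epsilon for the dataset's within factor."""
    s_c, _, _ = _prepare_covariance(data, basis)
    return epsilon_from_contrast_covariance(s_c)


# ---------------------------------------------------------------------------
# the split-plot engine
# ---------------------------------------------------------------------------


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Effect size SS_effect / (SS_effect + SS_error), in [0, 1]."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial eta squared undefined when both SS are zero")
    return ss_effect / (ss_effect + ss_error)


def _effect_label(between_subset: tuple[str, ...], within: str | None) -> str:
    parts = ([] if within is None else [within]) + list(between_subset)
    if within is not None:
        parts = [within] + list(between_subset)
        return " × ".join(parts)
    return " × ".join(between_subset) if between_subset else "Intercept"


def _f_row(
    effect: str,
    ss: float,
    df: float,
    ss_err: float,
    df_err: float,
    stratum: str,
    eps: float | None = None,
) -> AnovaEffectRow:
    ms = ss / df if df > 0 else float("nan")
    ms_err = ss_err / df_err if df_err > 0 else float("nan")
    if not np.isfinite(ms_err) or ms_err <= 0.0:
        f = p = float("nan")
    else:
        f = ms / ms_err
        p = float(stats.f.sf(f, df, df_err))
    try:
        eta = partial_eta_squared(ss, ss_err)
    except ValueError:
        eta = float("nan")
    row = dict(effect=effect, ss=ss, df=df, ms=ms, f=f, p=p, partial_eta_sq=eta, stratum=stratum)
    if eps is not None:
        df_gg, err_gg = df * eps, df_err * eps
        p_gg = float(stats.f.sf(f, df_gg, err_gg)) if np.isfinite(f) else float("nan")
        row.update(df_gg=df_gg, error_df_gg=err_gg, p_gg=p_gg)
    return AnovaEffectRow(**row)


def fit_mixed_anova(data: LongDataset, alpha: float = 0.05) -> AnovaResult:
    """Fit the split-plot mixed ANOVA and return the full decomposition.

    Emits the between stratum (Intercept, each between factor, their
    interaction, Error) followed by the within stratum (the within factor, its
    interactions with each between term, Error), with Greenhouse-Geisser
    corrected df and p on every within row. Units with incomplete
    within-profiles are excluded listwise and reported in ``excluded_units``.
    Raises if any observed between-cell has fewer than 2 units.
    """
    wide, labels, within_levels, excluded = _pivot(data)
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    # numerical floor: SS below this are rounding residue of an exact zero
    ss_floor = 1e-12 * max(1.0, float(np.sum(y * y)))

    # between-factor codings
    codes: list[np.ndarray] = []
    level_lists: list[list] = []
    for col in data.between:
        idx, levels = _factor_codes(labels[col])
        codes.append(idx)
        level_lists.append(levels)
    cell_ids = labels.astype(str).agg("|".join, axis=1).to_numpy()
    cells, cell_counts = np.unique(cell_ids, return_counts=True)
    if (cell_counts < 2).any():
        small = cells[cell_counts < 2]
        raise ValueError(f"between-cell(s) with fewer than 2 units: {list(small)}")
    n_cells = len(cells)

    coded = [
        _sum_to_zero_coding(len(levels))[idx]
        for idx, levels in zip(codes, level_lists)
    ]  # each (N, l_f - 1)

    between_subsets = [
        subset
        for r in range(1, len(data.between) + 1)
        for subset in itertools.combinations(range(len(data.between)), r)
    ]

    # ---- between stratum: OLS on unit means, SS scaled by k
    m = y.mean(axis=1)
    ones = np.ones((n, 1))
    term_cols: dict[str, np.ndarray] = {"Intercept": ones}
    for subset in between_subsets:
        label = _effect_label(tuple(data.between[i] for i in subset), None)
        term_cols[label] = _interaction_columns([coded[i] for i in subset])
    x_full = np.hstack(list(term_cols.values()))
    sse_full_b = _sse(x_full, m)
    ss_error_b = sse_full_b * k
    if ss_error_b < ss_floor:
        ss_error_b = 0.0
    df_error_b = n - n_cells

    rows: list[AnovaEffectRow] = []
    for label, cols in term_cols.items():
        others = np.hstack([c for lab, c in term_cols.items() if lab != label])
        ss = (_sse(others, m) - sse_full_b) * k
        ss = max(ss, 0.0)
        if ss < ss_floor:
            ss = 0.0
        rows.append(_f_row(label, ss, cols.shape[1], ss_error_b, df_error_b, "between"))
    rows.append(
        AnovaEffectRow(
            effect="Error",
            ss=ss_error_b,
            df=df_error_b,
            ms=ss_error_b / df_error_b if df_error_b else float("nan"),
            f=float("nan"),
            p=float("nan"),
            partial_eta_sq=float("nan"),
            stratum="error",
        )
    )

    sphericity: SphericityResult | None = None
    if k >= 2:
        basis = _orthonormal_contrasts(k)
        s_c, n_e, _ = (
            _pooled_contrast_covariance(y, cell_ids, basis)[0],
            df_error_b,
            k,
        )
        sphericity = _sphericity_from_cov(s_c, n_e, k)
        eps = sphericity.epsilon_gg

        # ---- within stratum: OLS on deviations from unit means
        d = (y - m[:, None]).ravel()  # unit-major
        cw = _sum_to_zero_coding(k)
        t_idx = np.tile(np.arange(k), n)
        zw = cw[t_idx]  # (N*k, k-1)
        w_term_cols: dict[str, np.ndarray] = {data.within: zw}
        for subset in between_subsets:
            label = _effect_label(tuple(data.between[i] for i in subset), data.within)
            bcols = _interaction_columns([coded[i] for i in subset])
            bcols_rep = np.repeat(bcols, k, axis=0)
            w_term_cols[label] = _interaction_columns([zw, bcols_rep])
        xw_full = np.hstack(list(w_term_cols.values()))
        sse_full_w = _sse(xw_full, d)
        if sse_full_w < ss_floor:
            sse_full_w = 0.0
        df_error_w = (k - 1) * (n - n_cells)
        for label, cols in w_term_cols.items():
            others = np.hstack([c for lab, c in w_term_cols.items() if lab != label])
            ss = max(_sse(others, d) - sse_full_w, 0.0)
            if ss < ss_floor:
                ss = 0.0
            rows.append(
                _f_row(label, ss, cols.shape[1], sse_full_w, df_error_w, "within", eps=eps)
            )
        rows.append(
            AnovaEffectRow(
                effect=f"Error ({data.within})",
                ss=sse_full_w,
                df=df_error_w,
                ms=sse_full_w / df_error_w if df_error_w else float("nan"),
                f=float("nan"),
                p=float("nan"),
                partial_eta_sq=float("nan"),
                stratum="error",
            )
        )

    return AnovaResult(
        rows=tuple(rows),
        sphericity=sphericity,
        n_units=n,
        excluded_units=excluded,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# post-hoc comparisons
# ---------------------------------------------------------------------------


def posthoc_pairwise(
    data: LongDataset,
    factor: str,
    alpha: float = 0.05,
    welch: bool = True,
) -> list[PairwiseComparison]:
    """Bonferroni-corrected pairwise comparisons for one factor.

    Within-factor pairs use paired t-tests on unit-level differences; pairs of
    a between factor use two-sample t-tests on unit means (Welch by default,
    pooled-variance optionally). The Bonferroni family is all pairs of the
    requested factor.
    """
    wide, labels, within_levels, _ = _pivot(data)
    results: list[tuple[str, str, float, float, float, str]] = []
    if factor == data.within:
        y = wide.to_numpy(dtype=float)
        n = y.shape[0]
        if n < 2:
            raise ValueError("paired comparisons need at least 2 units")
        for i, a in enumerate(within_levels):
            for b in within_levels[i + 1 :]:
                diff = y[:, i] - y[:, within_levels.index(b)]
                sd = diff.std(ddof=1)
                if sd == 0.0:
                    t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
                else:
                    t = diff.mean() / (sd / np.sqrt(n))
                    p = float(2 * stats.t.sf(abs(t), n - 1))
                results.append((str(a), str(b), float(t), float(n - 1), p, "paired"))
    elif factor in data.between:
        m = wide.to_numpy(dtype=float).mean(axis=1)
        groups: dict = {}
        for value, mean in zip(labels[factor], m):
            groups.setdefault(value, []).append(mean)
        levels = list(groups)
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                xa, xb = np.asarray(groups[a]), np.asarray(groups[b])
                if len(xa) < 2 or len(xb) < 2:
                    raise ValueError(f"level with fewer than 2 units in pair ({a}, {b})")
                res = stats.ttest_ind(xa, xb, equal_var=not welch)
                df = res.df if hasattr(res, "df") else len(xa) + len(xb) - 2
                kind = "welch" if welch else "pooled"
                results.append((str(a), str(b), float(res.statistic), float(df), float(res.pvalue), kind))
    else:
        raise ValueError(f"unknown factor {factor!r}; expected {data.within} or one of {data.between}")

    mfam = len(results)
    out = []
    for a, b, t, df, p, kind in results:
        out.append(
            PairwiseComparison(
                level_a=a,
                level_b=b,
                t=t,
                df=df,
                p_raw=p,
                p_adjusted=min(1.0, mfam * p),
                reject=p <= alpha / mfam,
                kind=kind,
            )
        )
    return out
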