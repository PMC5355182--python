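"""Race / kernel-color / altitude association analyses.

Two per-column association screens against a categorical grouping
(race or kernel color), both corrected by Benjamini–Hochberg FDR over the
whole group × column family:

* Welch t-tests of the z-score in-group vs all other accessions;
* likelihood-ratio (G-statistic) contingency tests of allele presence
  (z >= 1) vs group membership, G = 2 * sum O * ln(O/E), chi-square tail.

Plus a forward-stepwise ordinary least squares regression of collection
altitude (meters above sea level, MASL) on the z-scores, with a
configurable entry criterion (BIC by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .marker_matrix import AccessionMatrix, BulkMatrix, Matrix, collapse_bulks

DEFAULT_FDR_LEVEL = 0.001  # the "FDR <= 0.1%" screening level
DEFAULT_MIN_GROUP_SIZE = 10  # only groups with >= 10 accessions are tested


def _eligible_groups(groups: pd.Series, min_size: int) -> list:
    counts = groups.dropna().value_counts()
    n = groups.notna().sum()
    return [
        g
        for g, c in counts.items()
        if c >= max(min_size, 2) and (n - c) >= 2
    ]


def _bh(table: pd.DataFrame, fdr_level: float) -> pd.DataFrame:
    tested = table["p_value"].notna() & (table["note"] == "")
    q = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if tested.any():
        rej, qvals, *_ = multipletests(
            table.loc[tested, "p_value"], alpha=fdr_level, method="fdr_bh"
        )
        q[tested.to_numpy()] = qvals
        sig[tested.to_numpy()] = qvals <= fdr_level
    table["fdr_q"] = q
    table["significant"] = sig
    return table


def group_allele_ttests(
    a: AccessionMatrix,
    groups: pd.Series,
    fdr_level: float = DEFAULT_FDR_LEVEL,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Welch t-tests of z in-group vs others, per group x column, BH-corrected.

    ``groups`` maps accession id to a categorical label (NaN = unclassified,
    excluded). Groups smaller than ``min_size`` are not tested. Columns
    constant across all accessions get p = 1 and a note, never significant.
    Returns a tidy DataFrame with one row per (group, column).
    """
    g = groups.reindex(a.data.index)
    rows = []
    zcols = a.data.to_numpy(dtype=float)
    const = np.ptp(zcols, axis=0) == 0
    for grp in _eligible_groups(g, min_size):
        in_mask = (g == grp).to_numpy()
        out_mask = g.notna().to_numpy() & ~in_mask
        for j, col in enumerate(a.columns):
            zin, zout = zcols[in_mask, j], zcols[out_mask, j]
            mean_in, mean_out = float(zin.mean()), float(zout.mean())
            if const[j]:
                rows.append(
                    dict(
                        group=grp,
                        column=col,
                        mean_in_group=mean_in,
                        mean_in_others=mean_out,
                        t_statistic=np.nan,
                        p_value=1.0,
                        direction="+" if mean_in > mean_out else "-",
                        note="constant column; no test",
                    )
                )
                continue
            res = stats.ttest_ind(zin, zout, equal_var=False)
            rows.append(
                dict(
                    group=grp,
                    column=col,
                    mean_in_group=mean_in,
                    mean_in_others=mean_out,
                    t_statistic=float(res.statistic),
                    p_value=float(res.pvalue),
                    direction="+" if mean_in > mean_out else "-",
                    note="",
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "group",
            "column",
            "mean_in_group",
            "mean_in_others",
            "t_statistic",
            "p_value",
            "direction",
            "note",
        ],
    )
    return _bh(table, fdr_level)


def g_test(table: np.ndarray) -> tuple[float, int, float]:
    """Likelihood-ratio (G) test of independence on a contingency table.

    G = 2 * sum over non-zero cells of O * ln(O / E), df = (r-1)(c-1),
    p from the chi-square tail. Raises on a degenerate margin.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("contingency table must be a 2-D nonnegative array")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate margin in contingency table")
    expected = row @ col / total
    nz = obs > 0
    g = 2.0 * float((obs[nz] * np.log(obs[nz] / expected[nz])).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return g, df, float(stats.chi2.sf(g, df))


def group_allele_gtests(
    m: Matrix,
    groups: pd.Series,
    fdr_level: float = DEFAULT_FDR_LEVEL,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
    dichotomize: bool = True,
) -> pd.DataFrame:
    """G-statistic contingency tests of allele presence vs group membership.

    A bulk matrix is collapsed to z first. With ``dichotomize`` (default),
    each column is scored present (z >= 1) vs absent and tested in a 2x2
    table per group; ``dichotomize=False`` uses the full 2 x (B+1) table of
    observed z levels. Degenerate margins (a column present in all or no
    accessions) are skipped with a note.
    """
    a = collapse_bulks(m) if isinstance(m, BulkMatrix) else m
    g = groups.reindex(a.data.index)
    z = a.data.to_numpy()
    rows = []
    for grp in _eligible_groups(g, min_size):
        in_mask = (g == grp).to_numpy()
        out_mask = g.notna().to_numpy() & ~in_mask
        for j, col in enumerate(a.columns):
            zin, zout = z[in_mask, j], z[out_mask, j]
            rate_in = float((zin >= 1).mean())
            rate_out = float((zout >= 1).mean())
            if dichotomize:
                tab = np.array(
                    [
                        [(zin >= 1).sum(), (zin == 0).sum()],
                        [(zout >= 1).sum(), (zout == 0).sum()],
                    ],
                    dtype=float,
                )
            else:
                levels = np.arange(a.bulks_per_accession + 1)
                tab = np.array(
                    [[(zin == k).sum() for k in levels],
                     [(zout == k).sum() for k in levels]],
                    dtype=float,
                )
                tab = tab[:, tab.sum(axis=0) > 0]
            base = dict(
                group=grp,
                column=col,
                presence_in_group=rate_in,
                presence_in_others=rate_out,
                direction="+" if rate_in > rate_out else "-",
            )
            try:
                G, df, p = g_test(tab)
            except ValueError:
                rows.append(
                    dict(
                        **base,
                        G_statistic=np.nan,
                        df=0,
                        p_value=np.nan,
                        note="degenerate margin; test skipped",
                    )
                )
                continue
            rows.append(dict(**base, G_statistic=G, df=df, p_value=p, note=""))
    table = pd.DataFrame(
        rows,
        columns=[
            "group",
            "column",
            "presence_in_group",
            "presence_in_others",
            "direction",
            "G_statistic",
            "df",
            "p_value",
            "note",
        ],
    )
    return _bh(table, fdr_level)


@dataclass
class MaslModel:
    """Forward-selected linear model of altitude on marker/allele z-scores."""

    intercept: float
    coefficients: pd.Series  # beta_j, meters per z unit
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    r_squared: float
    criterion: str
    criterion_value: float
    selection_path: pd.DataFrame  # step, column, criterion value, action
    notes: list[str] = field(default_factory=list)

    def predict(self, a: AccessionMatrix) -> pd.Series:
        z = a.data[self.coefficients.index].to_numpy(dtype=float)
        return pd.Series(
            self.intercept + z @ self.coefficients.to_numpy(),
            index=a.data.index,
            name="masl_predicted",
        )


def _fit_ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _criterion_value(fit, criterion: str) -> float:
    return float(fit.bic if criterion == "bic" else fit.aic)


def masl_regression(
    a: AccessionMatrix,
    masl: pd.Series,
    criterion: str = "bic",
    max_terms: int | None = None,
    p_enter: float = 0.05,
) -> MaslModel:
    """Forward stepwise OLS of MASL on the z-score columns.

    Starting from the intercept-only model, at each step the candidate
    column that most improves the criterion (lower BIC/AIC, or smallest
    entry p-value below ``p_enter`` for ``criterion="pvalue"``) is added;
    selection stops when no candidate improves, ``max_terms`` is reached,
    or degrees of freedom run out. Candidates that would make the design
    rank-deficient are skipped with a note.
    """
    if criterion not in {"bic", "aic", "pvalue"}:
        raise ValueError("criterion must be 'bic', 'aic' or 'pvalue'")
    y_full = masl.reindex(a.data.index)
    if y_full.isna().any():
        raise ValueError(
            f"MASL missing for accession(s): {list(y_full.index[y_full.isna()])}"
        )
    y = y_full.to_numpy(dtype=float)
    zdf = a.data.astype(float)
    n = len(y)
    candidates = [c for c in zdf.columns if zdf[c].nunique() > 1]
    selected: list[str] = []
    notes: list[str] = []
    path = []

    current_fit = _fit_ols(y, np.empty((n, 0)))
    current_score = (
        _criterion_value(current_fit, criterion) if criterion != "pvalue" else np.inf
    )
    path.append(
        dict(step=0, column="(intercept)", criterion_value=float(current_fit.bic)
             if criterion != "pvalue" else np.nan, action="start")
    )

    limit = max_terms if max_terms is not None else len(candidates)
    while len(selected) < limit and candidates:
        if n <= len(selected) + 2:
            notes.append("stopped: insufficient degrees of freedom")
            break
        X_sel = zdf[selected].to_numpy()
        best = None  # (score, column, fit)
        for col in candidates:
            X_try = np.column_stack([X_sel, zdf[col].to_numpy()])
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), X_try])) < (
                X_try.shape[1] + 1
            ):
                continue  # collinear with already-selected terms
            fit = _fit_ols(y, X_try)
            if criterion == "pvalue":
                score = float(fit.pvalues[-1])
            else:
                score = _criterion_value(fit, criterion)
            if best is None or score < best[0]:
                best = (score, col, fit)
        if best is None:
            notes.append("stopped: all remaining candidates collinear")
            break
        score, col, fit = best
        accept = (
            score < p_enter if criterion == "pvalue" else score < current_score
        )
        if not accept:
            path.append(
                dict(step=len(selected) + 1, column=col, criterion_value=score,
                     action="rejected; stop")
            )
            break
        skipped = [
            c
            for c in candidates
            if c != col
            and np.linalg.matrix_rank(
                np.column_stack([np.ones(n), zdf[selected + [col, c]].to_numpy()])
            )
            < len(selected) + 3
        ]
        for c in skipped:
            notes.append(f"column {c} skipped: collinear with selected terms")
        selected.append(col)
        candidates = [c for c in candidates if c != col and c not in skipped]
        current_score = score if criterion != "pvalue" else np.inf
        current_fit = fit
        path.append(
            dict(step=len(selected), column=col, criterion_value=score,
                 action="added")
        )
        # an (essentially) exact fit leaves nothing for further terms
        tss = float(np.sum((y - y.mean()) ** 2))
        if float(current_fit.ssr) <= 1e-10 * tss + 1e-12:
            notes.append("stopped: residual variance exhausted")
            break

    names = ["(intercept)", *selected]
    params = pd.Series(current_fit.params, index=names)
    bse = pd.Series(current_fit.bse, index=names)
    tvals = pd.Series(current_fit.tvalues, index=names)
    pvals = pd.Series(current_fit.pvalues, index=names)
    return MaslModel(
        intercept=float(params.iloc[0]),
        coefficients=params.iloc[1:],
        std_errors=bse.iloc[1:],
        t_values=tvals.iloc[1:],
        p_values=pvals.iloc[1:],
        r_squared=float(current_fit.rsquared) if selected else 0.0,
        criterion=criterion,
        criterion_value=_criterion_value(current_fit, "bic")
        if criterion == "pvalue"
        else current_score,
        selection_path=pd.DataFrame(path),
        notes=notes,
    )
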