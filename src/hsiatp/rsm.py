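"""Central-composite-design response-surface analysis of the casing treatments.

Five casing-modification factors — soy lecithin, soy oil, treatment
duration, lactic acid and orange-extract addition — were varied in a
32-run rotatable central composite design (16 half-fraction cube points,
10 axial points at +/-2 coded units, 6 replicated centre points) with the
sausages' ATP content (log10 mol/L) as response.  This module rebuilds the
coded design from the uncoded factor settings, fits the full 21-term
quadratic by OLS, produces the Minitab-style sequential ANOVA with
lack-of-fit / pure-error decomposition, back-transforms to uncoded
coefficients, and exports prediction grids and the Pareto chart of
standardised effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Factor",
    "CCDesign",
    "RSMModel",
    "DEFAULT_FACTORS",
    "load_packaged_design",
    "build_design",
    "model_matrix",
    "term_names",
    "fit_quadratic",
    "anova",
    "predict",
    "surface_grid",
    "pareto_effects",
]


@dataclass(frozen=True)
class Factor:
    """One design factor: its centre level and the step of one coded unit."""

    name: str
    symbol: str
    centre: float
    step: float
    units: str = ""


DEFAULT_FACTORS: tuple[Factor, ...] = (
    Factor("soy_lecithin", "alpha", 3.33, 1.11, "g/100 g"),
    Factor("soy_oil", "beta", 1.875, 0.625, "g/100 g"),
    Factor("duration", "gamma", 75.0, 15.0, "min"),
    Factor("lactic_acid", "delta", 292.5, 22.5, "ul/15 g NaCl"),
    Factor("orange_extract", "epsilon", 0.28, 0.145, "g"),
)

CUBE_LEVELS = (-2.0, -1.0, 0.0, 1.0, 2.0)
CODED_SNAP_TOL = 0.25  # max distance (coded units) from a canonical level

# Published coded coefficients and standard errors of the casing-treatment
# study (constant; linear alpha..epsilon; squares; the ten two-way
# interactions in canonical order).  Used as generating ground truth in
# simulation-recovery checks, never as fitted output.
REFERENCE_CODED_COEFFICIENTS = np.array([
    -5.539,
    0.406, -0.081, -0.249, -0.054, -0.231,
    -0.027, -0.466, -0.410, 0.030, -0.450,
    -0.057, -0.411, -0.108, 0.948, -0.156, 0.006, -0.468, -0.204, 0.132, -0.517,
])
REFERENCE_COEFFICIENT_SE = np.array(
    [0.54] + [0.276] * 5 + [0.250] * 5 + [0.338] * 10
)


@dataclass
class CCDesign:
    """A coded central composite design with its measured responses."""

    factors: tuple[Factor, ...]
    coded: np.ndarray          # runs x 5, levels in {-2,-1,0,1,2}
    response: np.ndarray       # ATP, log10 mol/L
    run_ids: np.ndarray | None = None

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def centre_mask(self) -> np.ndarray:
        return np.all(self.coded == 0, axis=1)

    def uncoded(self) -> np.ndarray:
        centres = np.array([f.centre for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        return centres + self.coded * steps


def load_packaged_design() -> pd.DataFrame:
    """The packaged 32-run design table (factor settings + measured ATP)."""
    with resources.files("hsiatp.data").joinpath("ccd_design.csv").open() as fh:
        return pd.read_csv(fh)


def build_design(
    table: pd.DataFrame, factors: tuple[Factor, ...] = DEFAULT_FACTORS
) -> CCDesign:
    """Recover the coded design from uncoded (possibly rounded) settings.

    Printed factor settings carry rounding (the same coded orange-extract
    level appears as 0.41/0.42/0.43 g), so coded levels are inferred by
    snapping (x - centre)/step to the nearest canonical CCD level rather
    than trusting the uncoded digits; a run further than 0.25 coded units
    from every canonical level is rejected.
    """
    cols = [f.name for f in factors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"design table missing factor column(s) {missing}")
    X = table[cols].to_numpy(dtype=float)
    centres = np.array([f.centre for f in factors])
    steps = np.array([f.step for f in factors])
    z = (X - centres) / steps
    coded = np.rint(z)
    off = np.abs(z - coded)
    if np.any(off > CODED_SNAP_TOL):
        r, c = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"run {r + 1} factor {factors[c].name}: {off[r, c]:.3f} coded units "
            f"from the nearest canonical level"
        )
    if np.any(np.abs(coded) > 2):
        raise ValueError("coded level beyond +/-2 axial distance")
    response = (
        table["atp_measured"].to_numpy(dtype=float)
        if "atp_measured" in table.columns
        else np.full(len(table), np.nan)
    )
    run_ids = (
        table["treatment"].to_numpy() if "treatment" in table.columns else None
    )
    return CCDesign(factors=factors, coded=coded, response=response, run_ids=run_ids)


# ---------------------------------------------------------------------------
# Quadratic model
# ---------------------------------------------------------------------------

_PAIRS = list(itertools.combinations(range(5), 2))


def term_names(factors: tuple[Factor, ...] = DEFAULT_FACTORS) -> list[str]:
    """Names of the 21 model terms in their canonical entry order.

    Order: constant, 5 linear, 5 squares, 10 two-way interactions — the
    order in which the sequential ANOVA enters terms.
    """
    syms = [f.symbol for f in factors]
    names = ["Constant"] + syms + [f"{s}^2" for s in syms]
    names += [f"{syms[i]}*{syms[j]}" for i, j in _PAIRS]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Design matrix of the 21-term quadratic in coded units."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    cols = [np.ones(coded.shape[0])]
    cols += [coded[:, i] for i in range(5)]
    cols += [coded[:, i] ** 2 for i in range(5)]
    cols += [coded[:, i] * coded[:, j] for i, j in _PAIRS]
    return np.column_stack(cols)


@dataclass
class RSMModel:
    """The fitted quadratic response surface in coded and uncoded forms."""

    design: CCDesign
    coefficients: np.ndarray       # 21 coded coefficients
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    df_resid: int
    sigma2: float
    uncoded_coefficients: np.ndarray = field(default=None)
    degenerate: bool = False       # zero residual variance (noise-free fit)

    @property
    def sse(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def sst(self) -> float:
        y = self.design.response
        return float(((y - y.mean()) ** 2).sum())

    @property
    def r_squared(self) -> float:
        return 1.0 - self.sse / self.sst

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": term_names(self.design.factors),
                "coefficient": self.coefficients,
                "se": self.se,
                "t": self.t_values,
                "p": self.p_values,
                "uncoded": self.uncoded_coefficients,
            }
        )


def _uncode_coefficients(theta: np.ndarray, factors: tuple[Factor, ...]) -> np.ndarray:
    """Algebraic back-transform of coded coefficients to natural units.

    Substituting z_i = (x_i - c_i)/s_i into the coded quadratic and
    collecting terms in x gives exact natural-unit coefficients, so coded
    and uncoded predictions agree to machine precision (unlike re-deriving
    them from the rounded printed settings).
    """
    c = np.array([f.centre for f in factors])
    s = np.array([f.step for f in factors])
    b0 = theta[0]
    bl = theta[1:6]
    bq = theta[6:11]
    bi = {pair: theta[11 + k] for k, pair in enumerate(_PAIRS)}
    const = (
        b0
        - np.sum(bl * c / s)
        + np.sum(bq * c**2 / s**2)
        + sum(bi[(i, j)] * c[i] * c[j] / (s[i] * s[j]) for i, j in _PAIRS)
    )
    linear = np.empty(5)
    for i in range(5):
        cross = sum(
            bi[tuple(sorted((i, j)))] * c[j] / (s[i] * s[j]) for j in range(5) if j != i
        )
        linear[i] = bl[i] / s[i] - 2 * bq[i] * c[i] / s[i] ** 2 - cross
    quad = bq / s**2
    inter = np.array([bi[(i, j)] / (s[i] * s[j]) for i, j in _PAIRS])
    return np.concatenate([[const], linear, quad, inter])


def fit_quadratic(design: CCDesign) -> RSMModel:
    """OLS fit of the full quadratic; SE/t/p on the residual 11 df.

    With 32 runs and 21 terms the residual has 11 degrees of freedom;
    p-values are two-sided from t(11).  A noise-free response (SSE = 0)
    yields infinite t statistics and is flagged ``degenerate`` rather than
    raising, so exact-recovery checks remain expressible.
    """
    M = model_matrix(design.coded)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("model matrix rank-deficient: design does not support 21 terms")
    y = design.response
    if np.any(~np.isfinite(y)):
        raise ValueError("design has missing responses")
    res = sm.OLS(y, M).fit()
    df_resid = int(res.df_resid)
    sse = float(res.ssr)
    sigma2 = sse / df_resid if df_resid > 0 else np.nan
    degenerate = sse <= 1e-20
    if degenerate:
        se = np.zeros(M.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_vals = np.where(res.params != 0, np.inf, np.nan)
        p_vals = np.zeros(M.shape[1])
    else:
        se = np.asarray(res.bse)
        t_vals = np.asarray(res.tvalues)
        p_vals = np.asarray(res.pvalues)
    model = RSMModel(
        design=design,
        coefficients=np.asarray(res.params),
        se=se,
        t_values=t_vals,
        p_values=p_vals,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        df_resid=df_resid,
        sigma2=sigma2,
        degenerate=degenerate,
    )
    model.uncoded_coefficients = _uncode_coefficients(model.coefficients, design.factors)
    return model


def anova(model: RSMModel) -> pd.DataFrame:
    """Sequential (type-I) ANOVA with lack-of-fit / pure-error split.

    Terms enter in the canonical order (linear, squares, interactions);
    each term's sequential SS is the drop in residual SS when it joins the
    growing model.  Adjusted (type-III) SS is the increase in residual SS
    when that term alone is removed from the full model.  Pure error is the
    within-replicate SS of runs sharing identical coded settings (the six
    centre points here, 5 df); lack of fit is the remainder of the residual
    (6 df), tested by F against pure error.  Contribution % = SeqSS /
    TotalSS x 100.
    """
    design = model.design
    M = model_matrix(design.coded)
    y = design.response
    names = term_names(design.factors)
    n_terms = M.shape[1]

    def rss(cols: list[int]) -> float:
        beta, *_ = np.linalg.lstsq(M[:, cols], y, rcond=None)
        r = y - M[:, cols] @ beta
        return float(r @ r)

    sst = model.sst
    seq = np.empty(n_terms)
    prev = float(((y - y.mean()) ** 2).sum())  # after the constant alone
    seq[0] = np.nan
    for k in range(1, n_terms):
        cur = rss(list(range(k + 1)))
        seq[k] = prev - cur
        prev = cur
    adj = np.empty(n_terms)
    adj[0] = np.nan
    sse = model.sse
    for k in range(1, n_terms):
        adj[k] = rss([c for c in range(n_terms) if c != k]) - sse

    # pure error: replicate groups of identical coded rows
    _, inverse = np.unique(design.coded, axis=0, return_inverse=True)
    pe = 0.0
    df_pe = 0
    for g in np.unique(inverse):
        grp = y[inverse == g]
        if grp.size > 1:
            pe += float(((grp - grp.mean()) ** 2).sum())
            df_pe += grp.size - 1
    rows = []
    for k in range(1, n_terms):
        rows.append(
            {
                "term": names[k],
                "df": 1,
                "seq_ss": seq[k],
                "contribution_pct": 100.0 * seq[k] / sst,
                "adj_ss": adj[k],
                "p": model.p_values[k],
            }
        )
    rows.append(
        {
            "term": "Error",
            "df": model.df_resid,
            "seq_ss": sse,
            "contribution_pct": 100.0 * sse / sst,
            "adj_ss": sse,
            "p": np.nan,
        }
    )
    if df_pe > 0:
        lof = sse - pe
        df_lof = model.df_resid - df_pe
        if df_lof > 0 and pe > 0:
            f_lof = (lof / df_lof) / (pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            p_lof = np.nan
        rows.append(
            {"term": "Lack-of-fit", "df": df_lof, "seq_ss": lof,
             "contribution_pct": 100.0 * lof / sst, "adj_ss": lof, "p": p_lof}
        )
        rows.append(
            {"term": "Pure Error", "df": df_pe, "seq_ss": pe,
             "contribution_pct": 100.0 * pe / sst, "adj_ss": pe, "p": np.nan}
        )
    else:
        import warnings

        warnings.warn("no replicate runs: pure-error row omitted", stacklevel=2)
    rows.append(
        {"term": "Total", "df": design.n_runs - 1, "seq_ss": sst,
         "contribution_pct": 100.0, "adj_ss": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


def predict(
    model: RSMModel, settings: np.ndarray, coded: bool = True, warn_extrapolation: bool = True
) -> np.ndarray:
    """Evaluate the quadratic at factor settings (coded or natural units)."""
    settings = np.atleast_2d(np.asarray(settings, dtype=float))
    if settings.shape[1] != 5:
        raise ValueError("settings must have 5 factor columns")
    if coded:
        z = settings
    else:
        centres = np.array([f.centre for f in model.design.factors])
        steps = np.array([f.step for f in model.design.factors])
        z = (settings - centres) / steps
    if warn_extrapolation and np.any(np.abs(z) > 2 + 1e-9):
        import warnings

        warnings.warn("settings outside the +/-2 coded design region", stacklevel=2)
    return model_matrix(z) @ model.coefficients


def surface_grid(
    model: RSMModel,
    factor_pair: tuple[int, int] = (0, 4),
    others: np.ndarray | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Prediction grid over +/-2 coded units of a factor pair.

    Remaining factors sit at their centre (coded 0) unless ``others`` gives
    coded settings.  Returns a long-form frame (coded and natural units of
    the pair, plus the prediction) ready for surface/contour plotting.
    """
    i, j = factor_pair
    if i == j:
        raise ValueError("factor pair must name two distinct factors")
    g = np.linspace(-2.0, 2.0, n_grid)
    zi, zj = np.meshgrid(g, g, indexing="ij")
    base = np.zeros(5) if others is None else np.asarray(others, dtype=float)
    pts = np.tile(base, (n_grid * n_grid, 1))
    pts[:, i] = zi.ravel()
    pts[:, j] = zj.ravel()
    pred = predict(model, pts, coded=True, warn_extrapolation=False)
    fi, fj = model.design.factors[i], model.design.factors[j]
    return pd.DataFrame(
        {
            f"{fi.name}_coded": pts[:, i],
            f"{fj.name}_coded": pts[:, j],
            fi.name: fi.centre + pts[:, i] * fi.step,
            fj.name: fj.centre + pts[:, j] * fj.step,
            "atp_predicted": pred,
        }
    )


def pareto_effects(model: RSMModel) -> pd.DataFrame:
    """Standardised effects |t| per model term, largest first.

    The reference line is the two-sided critical value t(df_resid, 0.975);
    terms whose |t| exceed it are significant at the 5% level.  On a
    degenerate (noise-free) fit the t statistics are infinite and the frame
    carries the model's ``degenerate`` flag instead of a usable ranking.
    """
    names = term_names(model.design.factors)[1:]
    t_abs = np.abs(model.t_values[1:])
    order = np.argsort(-t_abs, kind="stable")
    critical = float(stats.t.ppf(0.975, model.df_resid)) if model.df_resid > 0 else np.nan
    out = pd.DataFrame(
        {
            "term": [names[k] for k in order],
            "abs_t": t_abs[order],
            "critical_t": critical,
            "significant": t_abs[order] > critical,
        }
    )
    out.attrs["degenerate"] = model.degenerate
    return out


def export_tables(model: RSMModel, out_dir: str | Path) -> dict[str, Path]:
    """Write coefficient, ANOVA, surface-grid and Pareto CSVs to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coefficients": out_dir / "rsm_coefficients.csv",
        "anova": out_dir / "rsm_anova.csv",
        "surface": out_dir / "rsm_surface_lecithin_orange.csv",
        "pareto": out_dir / "rsm_pareto.csv",
    }
    model.coefficient_table().to_csv(paths["coefficients"], index=False)
    anova(model).to_csv(paths["anova"], index=False)
    surface_grid(model).to_csv(paths["surface"], index=False)
    pareto_effects(model).to_csv(paths["pareto"], index=False)
    return paths
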