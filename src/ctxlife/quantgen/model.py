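"""REML variance-component models for replicated inbred-line designs.

The central model partitions phenotypic variation in a panel of inbred
lines reared in multiple contexts (two sexes crossed with several
thermal environments, with replicate rearing vials nested in
line x temperature)::

    Y = mu + S + T + SxT            (fixed)
        + L + LxS + LxT + LxSxT     (random, line and its interactions)
        + Rep(LxT) + SxRep(LxT)     (random, vial terms)
        + eps

All random effects are constant within a (line, sex, temperature, vial)
cell, so the full-data REML likelihood factorises exactly into (i) a
chi-square term for the pooled within-cell sum of squares, which
involves only the residual variance, and (ii) a Gaussian likelihood for
the cell means whose covariance matrix is block diagonal by line
(different lines share no random effects).  Each line block is a sum of
0/1 equality-indicator matrices weighted by the variance components,
plus ``sigma2_eps / n_cell`` on the diagonal.  Lines with identical
design patterns share one Cholesky factorisation per likelihood
evaluation, which makes full-panel fits (≈186 lines, ≈80k flies) run in
seconds.

Estimation is REML with non-negativity enforced by bound-constrained
optimisation (L-BFGS-B); standard errors come from the inverse observed
information (numerical Hessian of the REML log-likelihood), and random
terms can be tested by boundary-corrected likelihood-ratio tests
(50:50 mixture of chi2_0 and chi2_1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "ModelSpec",
    "VarianceComponentsModel",
    "VarianceComponentsResults",
    "NonConvergenceError",
]

# canonical term names
RANDOM_TERMS = (
    "line",
    "line:sex",
    "line:temperature",
    "line:sex:temperature",
    "vial",
    "sex:vial",
)
FIXED_TERMS = ("sex", "temperature", "sex:temperature")


class NonConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimiser diagnostics."""


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed and random terms enter the mixed model.

    ``vial`` denotes replicate vial nested in line x temperature
    (``Rep(LxT)``) and ``sex:vial`` its interaction with sex.
    """

    response: str = "lifespan_days"
    fixed: tuple[str, ...] = ("sex", "temperature", "sex:temperature")
    random: tuple[str, ...] = (
        "line",
        "line:sex",
        "line:temperature",
        "line:sex:temperature",
        "vial",
        "sex:vial",
    )

    def __post_init__(self):
        for t in self.fixed:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random:
            if t not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")
        if "line" not in self.random and any(
            t.startswith("line:") for t in self.random
        ):
            raise ValueError("line interactions require 'line' in the model")
        if "sex:vial" in self.random and "vial" not in self.random:
            raise ValueError("'sex:vial' requires 'vial' in the model")
        if "sex:temperature" in self.fixed and not (
            "sex" in self.fixed and "temperature" in self.fixed
        ):
            raise ValueError("'sex:temperature' requires both main effects")

    # -- convenience constructors matching the standard reduced models --

    @classmethod
    def full(cls, response: str = "lifespan_days", vial_terms: bool = True):
        """Full cross-classified model over both sexes and all temperatures."""
        random = [
            "line",
            "line:sex",
            "line:temperature",
            "line:sex:temperature",
        ]
        if vial_terms:
            random += ["vial", "sex:vial"]
        return cls(response=response, fixed=FIXED_TERMS, random=tuple(random))

    @classmethod
    def by_temperature(cls, response: str = "lifespan_days", vial_terms: bool = True):
        """Two-sex model within one temperature (gives sigma2_L, sigma2_LS)."""
        random = ["line", "line:sex"]
        if vial_terms:
            random += ["vial", "sex:vial"]
        return cls(response=response, fixed=("sex",), random=tuple(random))

    @classmethod
    def by_sex(cls, response: str = "lifespan_days", vial_terms: bool = True):
        """One-sex model across temperatures (gives sigma2_L, sigma2_LT)."""
        random = ["line", "line:temperature"]
        if vial_terms:
            random += ["vial"]
        return cls(response=response, fixed=("temperature",), random=tuple(random))

    @classmethod
    def single_context(cls, response: str = "lifespan_days", vial_terms: bool = True):
        """One sex at one temperature (line + vial + error)."""
        random = ["line"]
        if vial_terms:
            random += ["vial"]
        return cls(response=response, fixed=(), random=tuple(random))

    def drop(self, term: str) -> "ModelSpec":
        if term not in self.random:
            raise ValueError(f"{term!r} not in model")
        if term == "line" and any(t.startswith("line:") for t in self.random):
            raise ValueError("cannot drop 'line' while its interactions remain")
        if term == "vial" and "sex:vial" in self.random:
            raise ValueError("cannot drop 'vial' while 'sex:vial' remains")
        return replace(self, random=tuple(t for t in self.random if t != term))


def _needs(term: str) -> set[str]:
    return set(term.split(":"))


@dataclass
class _Pattern:
    """Shared design of a group of lines: cell labels and indicators."""

    n_cells: int
    n_per_cell: np.ndarray          # (m,)
    indicators: list[np.ndarray]    # one (m, m) 0/1 matrix per random term
    X: np.ndarray                   # (m, p) fixed-effect design (cell level)
    line_rows: list[np.ndarray]     # row indices into the cell table per line


class VarianceComponentsModel:
    """REML estimation of crossed line / sex / temperature variance components.

    Parameters
    ----------
    data :
        Long-format table with one row per observation.  Required
        columns: ``line``, the response, plus ``sex`` / ``temperature`` /
        ``vial`` as referenced by the spec's terms.
    spec :
        Fixed and random structure; see :class:`ModelSpec`.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        needed = {"line", spec.response}
        for t in spec.fixed + spec.random:
            needed |= _needs(t) - {"line", "vial"}
        if any("vial" in _needs(t) for t in spec.random):
            needed.add("vial")
        missing = needed - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")

        df = data.dropna(subset=[spec.response]).copy()
        if len(df) == 0:
            raise ValueError("no non-missing observations")
        self.nobs = len(df)
        self._build(df)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str = "lifespan_days",
        fixed=("sex", "temperature", "sex:temperature"),
        random=RANDOM_TERMS,
    ) -> "VarianceComponentsModel":
        return cls(data, ModelSpec(response=response, fixed=tuple(fixed), random=tuple(random)))

    # ------------------------------------------------------------------
    def _build(self, df: pd.DataFrame) -> None:
        spec = self.spec
        use_vial = any("vial" in _needs(t) for t in spec.random)
        use_sex = "sex" in df.columns and (
            any("sex" in _needs(t) for t in spec.fixed + spec.random)
        )
        use_temp = "temperature" in df.columns and (
            any("temperature" in _needs(t) for t in spec.fixed + spec.random)
        )

        keys = ["line"]
        if use_sex:
            keys.append("sex")
        if use_temp:
            keys.append("temperature")
        if use_vial:
            keys.append("vial")
        self._cell_keys = keys

        # level-count sanity: the line factor needs >= 2 realised levels
        if df["line"].nunique() < 2:
            raise ValueError("need at least 2 lines for a random line effect")

        g = df.groupby(keys, observed=True, sort=True)[spec.response]
        cells = g.agg(["mean", "count"])
        ss = g.apply(lambda v: float(np.sum((v.to_numpy() - v.to_numpy().mean()) ** 2)))
        cells = cells.reset_index()
        cells["ss"] = ss.to_numpy()
        self.n_cells = len(cells)
        self.ssw = float(cells["ss"].sum())
        self.df_within = self.nobs - self.n_cells

        # factor codes at cell level
        def codes(col):
            return pd.Categorical(cells[col]).codes

        sex_c = codes("sex") if use_sex else np.zeros(len(cells), dtype=int)
        temp_c = codes("temperature") if use_temp else np.zeros(len(cells), dtype=int)
        if use_vial:
            tcol = cells["temperature"] if use_temp else np.zeros(len(cells), dtype=int)
            vial_c = pd.Categorical(
                list(zip(cells["line"], tcol, cells["vial"]))
            ).codes
        else:
            vial_c = np.zeros(len(cells), dtype=int)

        # fixed-effect design (treatment coding; full rank given parents)
        Xcols = [np.ones(len(cells))]
        sex_d = pd.get_dummies(sex_c, drop_first=True).to_numpy(float) if use_sex else np.empty((len(cells), 0))
        temp_d = pd.get_dummies(temp_c, drop_first=True).to_numpy(float) if use_temp else np.empty((len(cells), 0))
        if "sex" in spec.fixed and sex_d.shape[1]:
            Xcols.append(sex_d)
        if "temperature" in spec.fixed and temp_d.shape[1]:
            Xcols.append(temp_d)
        if "sex:temperature" in spec.fixed and sex_d.shape[1] and temp_d.shape[1]:
            inter = np.einsum("ij,ik->ijk", sex_d, temp_d).reshape(len(cells), -1)
            Xcols.append(inter)
        X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in Xcols])
        self.k_fixed = X.shape[1]

        # random-term labels at cell level
        term_labels = {}
        for t in spec.random:
            need = _needs(t)
            lab = np.zeros(len(cells), dtype=np.int64)
            if "sex" in need:
                lab = lab * (sex_c.max() + 1) + sex_c
            if "temperature" in need and "vial" not in need:
                lab = lab * (temp_c.max() + 1) + temp_c
            if "vial" in need:
                lab = lab * (vial_c.max() + 1) + vial_c
            term_labels[t] = lab
            # estimability: the term must have >= 2 realised levels overall
            n_lev = len(np.unique(lab)) if t not in ("line",) else cells["line"].nunique()
            if t == "line":
                continue
            if n_lev < 2:
                raise ValueError(f"random term {t!r} has < 2 realised levels")

        # group cells by line and build shared patterns
        line_codes = pd.Categorical(cells["line"]).codes
        y = cells["mean"].to_numpy(float)
        n_per = cells["count"].to_numpy(float)

        order = np.lexsort((vial_c, temp_c, sex_c, line_codes))
        line_codes = line_codes[order]
        y = y[order]
        n_per = n_per[order]
        X = X[order]
        sex_c, temp_c, vial_c = sex_c[order], temp_c[order], vial_c[order]
        for t in term_labels:
            term_labels[t] = term_labels[t][order]

        self._patterns: list[_Pattern] = []
        self._pattern_y: list[np.ndarray] = []   # (m, L) stacked means per pattern
        sig_map: dict = {}
        starts = np.flatnonzero(np.r_[True, np.diff(line_codes) != 0])
        bounds = np.r_[starts, len(line_codes)]
        for i in range(len(starts)):
            lo, hi = bounds[i], bounds[i + 1]
            rows = np.arange(lo, hi)
            # canonical within-line signature: context labels, vial dense
            # renumbering and cell sizes; lines sharing it share V and X
            vloc = vial_c[rows]
            _, vdense = np.unique(vloc, return_inverse=True)
            sig = (
                tuple(sex_c[rows]),
                tuple(temp_c[rows]),
                tuple(vdense),
                tuple(n_per[rows].astype(int)),
            )
            if sig not in sig_map:
                m = len(rows)
                inds = []
                for t in spec.random:
                    if t == "line":
                        inds.append(np.ones((m, m)))
                        continue
                    lab = term_labels[t][rows]
                    inds.append((lab[:, None] == lab[None, :]).astype(float))
                sig_map[sig] = len(self._patterns)
                self._patterns.append(
                    _Pattern(m, n_per[rows].copy(), inds, X[rows].copy(), [rows])
                )
                self._pattern_y.append([y[rows]])
            else:
                p = self._patterns[sig_map[sig]]
                p.line_rows.append(rows)
                self._pattern_y[sig_map[sig]].append(y[rows])
        self._pattern_y = [np.column_stack(v) for v in self._pattern_y]
        self.n_lines = len(starts)
        self._y_var = float(np.var(df[spec.response].to_numpy(), ddof=1)) if self.nobs > 1 else 0.0
        self._y = y

    # ------------------------------------------------------------------
    def _neg_reml(self, theta: np.ndarray) -> float:
        """Negative REML log-likelihood (up to an additive constant).

        ``theta`` = variance components in the order of ``spec.random``
        followed by the residual variance.
        """
        q = len(self.spec.random)
        sig = theta[:q]
        s2e = theta[q]
        if s2e <= 0 or np.any(sig < 0):
            return np.inf
        ll = 0.0
        if self.df_within > 0:
            ll -= 0.5 * (self.df_within * np.log(s2e) + self.ssw / s2e)
        p = self.k_fixed
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = 0.0
        for pat, Y in zip(self._patterns, self._pattern_y):
            V = s2e / pat.n_per_cell * np.eye(pat.n_cells)
            for s, M in zip(sig, pat.indicators):
                if s > 0:
                    V += s * M
            try:
                L = linalg.cholesky(V, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return np.inf
            nl = len(pat.line_rows)
            A = linalg.solve_triangular(L, pat.X, lower=True, check_finite=False)
            B = linalg.solve_triangular(L, Y, lower=True, check_finite=False)
            XtWX += nl * (A.T @ A)
            XtWy += A.T @ B.sum(axis=1)
            ytWy += float(np.sum(B * B))
            logdet += nl * 2.0 * float(np.sum(np.log(np.diag(L))))
        sgn, ldx = np.linalg.slogdet(XtWX)
        if sgn <= 0:
            return np.inf
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        quad = ytWy - float(beta @ XtWy)
        ll -= 0.5 * (logdet + ldx + quad)
        return -ll

    def _beta_cov(self, theta):
        """GLS fixed effects and covariance at given components."""
        q = len(self.spec.random)
        sig, s2e = theta[:q], theta[q]
        p = self.k_fixed
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        for pat, Y in zip(self._patterns, self._pattern_y):
            V = s2e / pat.n_per_cell * np.eye(pat.n_cells)
            for s, M in zip(sig, pat.indicators):
                if s > 0:
                    V += s * M
            L = linalg.cholesky(V, lower=True, check_finite=False)
            A = linalg.solve_triangular(L, pat.X, lower=True, check_finite=False)
            B = linalg.solve_triangular(L, Y, lower=True, check_finite=False)
            XtWX += len(pat.line_rows) * (A.T @ A)
            XtWy += A.T @ B.sum(axis=1)
        cov = np.linalg.pinv(XtWX)
        return cov @ XtWy, cov

    # ------------------------------------------------------------------
    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 500,
        compute_se: bool = True,
    ) -> "VarianceComponentsResults":
        """Maximise the REML likelihood under non-negativity constraints."""
        q = len(self.spec.random)
        yv = self._y_var
        if yv <= 0 or not np.isfinite(yv):
            # constant response: every component is zero, fit is degenerate
            return VarianceComponentsResults(
                self, np.zeros(q + 1), None, -np.inf, True, degenerate=True,
                message="constant response; all components zero",
            )
        scale = yv
        if start is None:
            s2e0 = self.ssw / self.df_within if self.df_within > 0 else 0.5 * yv
            s2e0 = max(s2e0, 1e-8 * yv)
            between = max(yv - s2e0, 0.1 * yv)
            start = np.r_[np.full(q, between / max(q, 1)), s2e0]
        th0 = np.asarray(start, float) / scale
        bounds = [(0.0, None)] * q + [(1e-10, None)]

        def f(t):
            return self._neg_reml(t * scale)

        res = optimize.minimize(
            f, th0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x * scale
        converged = bool(res.success) and np.isfinite(res.fun)
        if not np.isfinite(res.fun):
            raise NonConvergenceError(f"REML optimisation failed: {res.message}")
        cov_theta = None
        if compute_se and converged:
            cov_theta = self._hessian_cov(theta, scale)
        return VarianceComponentsResults(
            self, theta, cov_theta, -float(res.fun), converged, message=str(res.message)
        )

    def _hessian_cov(self, theta: np.ndarray, scale: float) -> np.ndarray | None:
        """Inverse observed information via a central-difference Hessian."""
        k = len(theta)
        t = theta / scale
        h = 1e-4 * np.maximum(t, 1e-2)
        H = np.zeros((k, k))
        f0 = self._neg_reml(theta)

        def fx(x):
            return self._neg_reml(np.maximum(x, 0.0) * scale)

        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    val = (fx(t + ei) - 2 * f0 + fx(t - ei)) / h[i] ** 2
                else:
                    val = (
                        fx(t + ei + ej) - fx(t + ei - ej)
                        - fx(t - ei + ej) + fx(t - ei - ej)
                    ) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cov = np.linalg.pinv(H) * scale**2
            except np.linalg.LinAlgError:
                return None
        return cov


class VarianceComponentsResults:
    """REML estimates, uncertainties and tests for a fitted model.

    Attributes
    ----------
    components : dict
        Estimated variance components (response units squared), keyed by
        term name plus ``"residual"``.
    se : dict
        Large-sample standard errors (NaN where the estimate sits on the
        zero boundary or the information matrix is singular).
    """

    def __init__(self, model, theta, cov_theta, loglik, converged,
                 degenerate=False, message=""):
        self.model = model
        self.spec = model.spec
        self.theta = np.asarray(theta, float)
        self.cov_theta = cov_theta
        self.loglik = loglik
        self.converged = converged
        self.degenerate = degenerate
        self.message = message
        q = len(self.spec.random)
        names = list(self.spec.random) + ["residual"]
        self.components = dict(zip(names, self.theta))
        if cov_theta is not None:
            d = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))
            self.se = {
                n: (float(d[i]) if self.theta[i] > 0 else np.nan)
                for i, n in enumerate(names)
            }
        else:
            self.se = {n: np.nan for n in names}
        self._lrt_cache: dict[str, tuple[float, float]] = {}

    # variance of the boundary convention: components already >= 0
    @property
    def sigma2(self) -> dict:
        return dict(self.components)

    @property
    def sigma2_resid(self) -> float:
        return float(self.components["residual"])

    def genetic_variance(self) -> float:
        """Sum of every line-containing component in the fitted model."""
        return float(
            sum(v for k, v in self.components.items() if "line" in _needs(k))
        )

    def lrt(self, term: str) -> tuple[float, float]:
        """Boundary-corrected REML likelihood-ratio test for one random term.

        Returns ``(LR, p)`` with ``p = 0.5 * P(chi2_1 > LR)`` (the 50:50
        chi2_0 / chi2_1 mixture appropriate for a variance on the
        boundary of its parameter space).
        """
        if term in self._lrt_cache:
            return self._lrt_cache[term]
        if term not in self.spec.random:
            raise ValueError(f"{term!r} not in model")
        # the reduced model legitimately omits a single term even when
        # higher-order interactions of the same factor stay in the model,
        # so bypass the constructor's parent check
        reduced_spec = object.__new__(ModelSpec)
        object.__setattr__(reduced_spec, "response", self.spec.response)
        object.__setattr__(reduced_spec, "fixed", self.spec.fixed)
        object.__setattr__(
            reduced_spec, "random",
            tuple(t for t in self.spec.random if t != term),
        )
        red = VarianceComponentsModel(self._source_frame(), reduced_spec).fit(
            compute_se=False
        )
        lr = max(0.0, 2.0 * (self.loglik - red.loglik))
        p = 0.5 * stats.chi2.sf(lr, 1) if lr > 0 else 1.0
        self._lrt_cache[term] = (lr, p)
        return lr, p

    def _source_frame(self):
        if not hasattr(self.model, "_data_ref"):
            raise RuntimeError(
                "source data not retained; refit via fit_variance_components "
                "to enable likelihood-ratio tests"
            )
        return self.model._data_ref

    def anova(self, lrt: bool = False) -> pd.DataFrame:
        """Variance-component table (optionally with LR tests)."""
        rows = []
        for name in list(self.spec.random) + ["residual"]:
            row = {
                "term": name,
                "sigma2": self.components[name],
                "se": self.se[name],
            }
            if lrt and name != "residual":
                lr, p = self.lrt(name)
                row["LR"], row["p"] = lr, p
            rows.append(row)
        return pd.DataFrame(rows)

    def fixed_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed-effect estimates and their covariance at the REML fit."""
        return self.model._beta_cov(self.theta)

    def summary(self) -> str:
        lines = [
            "REML variance components",
            "=" * 58,
            f"response: {self.spec.response}   "
            f"n_obs: {self.model.nobs}   lines: {self.model.n_lines}",
            f"fixed: {', '.join(self.spec.fixed) or '(intercept only)'}",
            f"REML log-likelihood: {self.loglik:.4f}   "
            f"converged: {self.converged}"
            + ("   DEGENERATE" if self.degenerate else ""),
            "-" * 58,
            f"{'term':<24}{'sigma2':>14}{'SE':>14}",
        ]
        for name in list(self.spec.random) + ["residual"]:
            lines.append(
                f"{name:<24}{self.components[name]:>14.5g}{self.se[name]:>14.4g}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<VarianceComponentsResults loglik={self.loglik:.3f} "
            f"converged={self.converged}>"
        )


def fit_variance_components(
    data: pd.DataFrame, spec: ModelSpec, **fit_kws
) -> VarianceComponentsResults:
    """Fit ``spec`` to ``data`` by REML, retaining the data for LR tests."""
    model = VarianceComponentsModel(data, spec)
    model._data_ref = data
    return model.fit(**fit_kws)
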