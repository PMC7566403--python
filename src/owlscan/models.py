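"""Maximum-likelihood codon models: the branch model and branch-site model A.

The interface follows the statsmodels convention: a model object is built
from data (`BranchModel(alignment, tree)`), `fit()` maximizes the likelihood
and returns a results object carrying the estimates, the paired null/
alternative fits, the likelihood-ratio test and a `summary()` table.

Branch lengths
--------------
By default the input branch lengths act as relative lengths and a single
global scale (expected substitutions per codon) is estimated jointly with
the model parameters under every hypothesis ("scale" mode). In
"per-branch" mode each length is first optimized under the one-ω model by
coordinate descent, then held fixed up to a free global scale during the
H0/H1 fits — mirroring the common practice of estimating the gene tree once
and re-using it for the nested tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .alignment import CodonAlignment
from .codon import build_codon_space, estimate_codon_freqs
from .likelihood import PruningEngine
from .tree import PhyloTree

__all__ = [
    "CodonModelParams",
    "BranchSiteParams",
    "FitResult",
    "BranchModel",
    "BranchSiteModel",
    "BranchModelResults",
    "BranchSiteModelResults",
    "log_likelihood",
    "fit_branch_model",
    "fit_branch_site",
    "lrt",
    "LRT_CRITICAL_05",
]

#: χ²₁ critical value at α = 0.05 used as the nominal significance cut-off.
LRT_CRITICAL_05 = chi2.ppf(0.95, df=1)

_KAPPA_BOUNDS = (math.log(1e-3), math.log(100.0))
_OMEGA_BOUNDS = (math.log(1e-6), math.log(999.0))
_SCALE_BOUNDS = (-8.0, 8.0)
_LOGIT_BOUNDS = (-10.0, 10.0)
_OMEGA2_BOUNDS = (math.log(1e-8), math.log(998.0))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    # clamped to the optimizer's box so warm-start round trips are exact
    p = min(max(p, 1e-12), 1 - 1e-12)
    return min(max(math.log(p / (1 - p)), _LOGIT_BOUNDS[0]), _LOGIT_BOUNDS[1])


@dataclass(frozen=True)
class CodonModelParams:
    """Branch-model parameters: one ω per branch class."""

    kappa: float
    pi: np.ndarray
    omega_map: dict  # {"background": ω0, "foreground": ω1}
    branch_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if abs(float(np.sum(self.pi)) - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if any(w < 0 for w in self.omega_map.values()):
            raise ValueError("omega values must be non-negative")


@dataclass(frozen=True)
class BranchSiteParams:
    """Branch-site model A parameters.

    Site classes: class 0 (prop p0) has ω0 on every branch; class 1 (p1) is
    neutral everywhere; classes 2a/2b (the remainder split proportionally to
    p0:p1) keep ω0 resp. 1 on the background but ω2 on the foreground.
    """

    kappa: float
    pi: np.ndarray
    p0: float
    p1: float
    omega0: float
    omega2: float
    branch_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.omega0 < 0 or self.omega2 < 0:
            raise ValueError("rates must be non-negative")
        if abs(float(np.sum(self.pi)) - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("invalid class proportions")

    @property
    def p2a(self) -> float:
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        return rest * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        return rest * self.p1 / (self.p0 + self.p1)


@dataclass
class FitResult:
    """Outcome of one maximized hypothesis."""

    lnL: float
    params: dict
    converged: bool
    n_restarts_used: int
    n_evaluations: int = 0


def log_likelihood(aln: CodonAlignment, tree: PhyloTree, params) -> float:
    """Log-likelihood of an alignment under explicit parameter values."""
    engine = PruningEngine(aln, tree, np.asarray(params.pi, dtype=float))
    if isinstance(params, CodonModelParams):
        return engine.lnl_branch(params.kappa,
                                 params.omega_map["background"],
                                 params.omega_map.get(
                                     "foreground", params.omega_map["background"]),
                                 scale=params.branch_scale)
    if isinstance(params, BranchSiteParams):
        return engine.lnl_branch_site(params.kappa, params.p0, params.p1,
                                      params.omega0, params.omega2,
                                      scale=params.branch_scale)
    raise TypeError(f"unsupported parameter object: {type(params)!r}")


def lrt(lnl0: float, lnl1: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic 2(lnL1 − lnL0) and its χ²_df upper tail.

    A negative statistic (numerically possible when the alternative fit
    under-converges) is clamped to 0 with a warning, since a nested null can
    never truly fit better.
    """
    if not (np.isfinite(lnl0) and np.isfinite(lnl1)):
        raise ValueError("log-likelihoods must be finite")
    stat = 2.0 * (lnl1 - lnl0)
    if stat < 0:
        if stat < -0.01:
            warnings.warn(
                f"negative LRT statistic {stat:.4g} clamped to 0 "
                "(alternative fit did not reach the null likelihood)",
                stacklevel=2,
            )
        stat = 0.0
    return stat, float(chi2.sf(stat, df))


class _Maximizer:
    """Bounded multi-start maximization with an evaluation counter."""

    def __init__(self, fun):
        self.fun = fun
        self.n_eval = 0

    def __call__(self, x):
        self.n_eval += 1
        return -self.fun(x)

    def run(self, starts, bounds):
        best = None
        used = 0
        for x0 in starts:
            used += 1
            res = minimize(self, np.asarray(x0, dtype=float), method="L-BFGS-B",
                           bounds=bounds)
            cand = (-res.fun, tuple(-v for v in res.x), res)
            if best is None or cand[:2] > best[:2]:
                best = cand
        lnl, _, res = best
        return res.x, lnl, bool(res.success), used, self.n_eval


class _CodonModelBase:
    def __init__(self, aln: CodonAlignment, tree: PhyloTree,
                 freq_method: str = "F3x4", lengths: str = "scale",
                 restarts: int = 3, branch_lengths: np.ndarray | None = None):
        if lengths not in ("scale", "per-branch"):
            raise ValueError("lengths must be 'scale' or 'per-branch'")
        self.aln = aln
        self.tree = tree
        self.freq_method = freq_method
        self.lengths_mode = lengths
        self.restarts = max(1, int(restarts))
        self.space = build_codon_space(1)
        self.pi = estimate_codon_freqs(aln, freq_method, self.space)
        self.engine = PruningEngine(aln, tree, self.pi, self.space)
        self._lengths = (np.asarray(branch_lengths, dtype=float)
                         if branch_lengths is not None else None)
        self._one_omega_fit: FitResult | None = None

    @property
    def branch_lengths(self) -> np.ndarray:
        """Relative branch lengths used by the fits (engine node order)."""
        if self._lengths is None:
            self._lengths = self.engine.base_lengths.copy()
            if self.lengths_mode == "per-branch":
                self._optimize_lengths()
        return self._lengths

    def one_omega_fit(self) -> FitResult:
        """Shared one-ω (null branch model) fit used to seed every hypothesis."""
        if self._one_omega_fit is None:
            lens = self.branch_lengths
            opt = _Maximizer(lambda x: self.engine.lnl_single(
                math.exp(x[0]), math.exp(x[1]), math.exp(x[2]), lengths=lens))
            starts = [
                (math.log(2.0), math.log(0.4), 0.0),
                (math.log(2.0), math.log(1.2), 0.0),
                (math.log(0.8), math.log(0.05), 0.0),
            ][: self.restarts]
            bounds = [_KAPPA_BOUNDS, _OMEGA_BOUNDS, _SCALE_BOUNDS]
            x, lnl, ok, used, nev = opt.run(starts, bounds)
            self._one_omega_fit = FitResult(
                lnL=lnl,
                params={"kappa": math.exp(x[0]), "omega": math.exp(x[1]),
                        "scale": math.exp(x[2])},
                converged=ok, n_restarts_used=used, n_evaluations=nev)
        return self._one_omega_fit

    def _optimize_lengths(self, sweeps: int = 2) -> None:
        """Coordinate-descent branch-length estimation under the one-ω model."""
        lens = self._lengths
        fit = None
        for _ in range(sweeps):
            # refresh (kappa, omega) at the current lengths
            opt = _Maximizer(lambda x: self.engine.lnl_single(
                math.exp(x[0]), math.exp(x[1]), 1.0, lengths=lens))
            x, _, _, _, _ = opt.run([(math.log(2.0), math.log(0.4))],
                                    [_KAPPA_BOUNDS, _OMEGA_BOUNDS])
            kappa, omega = math.exp(x[0]), math.exp(x[1])
            for b in self.engine.index.branch_ids:
                def f(t, _b=b):
                    trial = lens.copy()
                    trial[_b] = t
                    return -self.engine.lnl_single(kappa, omega, 1.0, lengths=trial)
                res = minimize_scalar(f, bounds=(1e-6, 10.0), method="bounded",
                                      options={"xatol": 1e-4})
                lens[b] = res.x
        self._one_omega_fit = None  # seeds must be refreshed


class BranchModel(_CodonModelBase):
    """Foreground/background ω contrast on a labeled tree.

    H0: one ω shared by all branches. H1: the flagged foreground branches
    take their own ω1 while the background keeps ω0.
    """

    def fit(self, hypothesis: str | None = None):
        """Fit H0, H1 or (default) both plus their likelihood-ratio test."""
        if hypothesis not in (None, "H0", "H1"):
            raise ValueError("hypothesis must be None, 'H0' or 'H1'")
        h0 = self._fit_h0()
        if hypothesis == "H0":
            return h0
        h1 = self._fit_h1(h0)
        if hypothesis == "H1":
            return h1
        stat, p = lrt(h0.lnL, h1.lnL)
        return BranchModelResults(self, h0, h1, stat, p)

    def _fit_h0(self) -> FitResult:
        base = self.one_omega_fit()
        if self.lengths_mode == "scale":
            return base
        # per-branch mode: lengths frozen, re-fit (kappa, omega, scale)
        lens = self.branch_lengths
        opt = _Maximizer(lambda x: self.engine.lnl_single(
            math.exp(x[0]), math.exp(x[1]), math.exp(x[2]), lengths=lens))
        start = (math.log(base.params["kappa"]), math.log(base.params["omega"]), 0.0)
        x, lnl, ok, used, nev = opt.run([start],
                                        [_KAPPA_BOUNDS, _OMEGA_BOUNDS, _SCALE_BOUNDS])
        return FitResult(lnl, {"kappa": math.exp(x[0]), "omega": math.exp(x[1]),
                               "scale": math.exp(x[2])}, ok, used, nev)

    def _fit_h1(self, h0: FitResult) -> FitResult:
        if not self.tree.foreground_branches():
            raise ValueError("H1 requires at least one foreground branch")
        lens = self.branch_lengths
        opt = _Maximizer(lambda x: self.engine.lnl_branch(
            math.exp(x[0]), math.exp(x[1]), math.exp(x[2]), math.exp(x[3]),
            lengths=lens))
        k0 = math.log(h0.params["kappa"])
        w0 = math.log(max(h0.params["omega"], 1e-6))
        s0 = math.log(h0.params["scale"])
        starts = [
            (k0, w0, w0, s0),                       # exactly the H0 optimum
            (k0, w0, math.log(max(2.5, 3 * h0.params["omega"])), s0),
            (k0, w0, math.log(max(h0.params["omega"] / 5, 1e-5)), s0),
        ][: self.restarts]
        bounds = [_KAPPA_BOUNDS, _OMEGA_BOUNDS, _OMEGA_BOUNDS, _SCALE_BOUNDS]
        x, lnl, ok, used, nev = opt.run(starts, bounds)
        return FitResult(lnl, {"kappa": math.exp(x[0]), "omega0": math.exp(x[1]),
                               "omega1": math.exp(x[2]), "scale": math.exp(x[3])},
                         ok, used, nev)


class BranchSiteModel(_CodonModelBase):
    """Branch-site model A: site classes with foreground-specific ω2.

    H0 fixes ω2 = 1 (no positive selection anywhere); H1 frees ω2 ≥ 1 on the
    foreground branch for the 2a/2b site classes.
    """

    def fit(self, hypothesis: str | None = None):
        if hypothesis not in (None, "H0", "H1"):
            raise ValueError("hypothesis must be None, 'H0' or 'H1'")
        if self.engine.index.fg_child is None:
            raise ValueError("branch-site model requires exactly one foreground branch")
        h0 = self._fit_h0()
        if hypothesis == "H0":
            return h0
        h1 = self._fit_h1(h0)
        if h1.lnL < h0.lnL:
            # ω2 → 1 closes onto H0, so the H1 supremum is at least lnL(H0);
            # report the boundary point when the search ends marginally below
            h1 = FitResult(h0.lnL, {**h0.params, "omega2": 1.0},
                           h1.converged, h1.n_restarts_used, h1.n_evaluations)
        if hypothesis == "H1":
            return h1
        stat, p = lrt(h0.lnL, h1.lnL)
        return BranchSiteModelResults(self, h0, h1, stat, p)

    def _xtop(self, x, omega2=None):
        s0, s1 = _sigmoid(x[1]), _sigmoid(x[2])
        p0, p1 = s0, (1 - s0) * s1
        return dict(kappa=math.exp(x[0]), p0=p0, p1=p1,
                    omega0=math.exp(x[3]),
                    omega2=(omega2 if omega2 is not None else 1.0 + math.exp(x[4])),
                    scale=math.exp(x[-1]))

    def _fit_h0(self) -> FitResult:
        base = self.one_omega_fit()
        lens = self.branch_lengths

        def f(x):
            p = self._xtop(np.concatenate([x[:4], [0.0], x[4:]]), omega2=1.0)
            return self.engine.lnl_branch_site(p["kappa"], p["p0"], p["p1"],
                                               p["omega0"], 1.0, p["scale"],
                                               lengths=lens)

        opt = _Maximizer(f)
        k0 = math.log(base.params["kappa"])
        w0 = math.log(min(max(base.params["omega"], 1e-5), 0.9))
        s0 = math.log(base.params["scale"])
        starts = [
            (k0, _logit(0.75), _logit(0.6), w0, s0),
            (k0, _logit(0.45), _logit(0.8), w0, s0),
            (k0, _logit(0.9), _logit(0.4), w0, s0),
        ][: self.restarts]
        bounds = [_KAPPA_BOUNDS, _LOGIT_BOUNDS, _LOGIT_BOUNDS,
                  (_OMEGA_BOUNDS[0], math.log(1.0)), _SCALE_BOUNDS]
        x, lnl, ok, used, nev = opt.run(starts, bounds)
        params = self._xtop(np.concatenate([x[:4], [0.0], x[4:]]), omega2=1.0)
        return FitResult(lnl, params, ok, used, nev)

    def _fit_h1(self, h0: FitResult) -> FitResult:
        lens = self.branch_lengths

        def f(x):
            p = self._xtop(x)
            return self.engine.lnl_branch_site(p["kappa"], p["p0"], p["p1"],
                                               p["omega0"], p["omega2"],
                                               p["scale"], lengths=lens)

        opt = _Maximizer(f)
        k0 = math.log(h0.params["kappa"])
        a0 = _logit(h0.params["p0"])
        b0 = _logit(h0.params["p1"] / max(1 - h0.params["p0"], 1e-6))
        w0 = math.log(max(h0.params["omega0"], 1e-6))
        s0 = math.log(h0.params["scale"])
        # the ω2 ≈ 1 anchor start sits on a flat boundary of the profile, so
        # an elevated-ω2 start is always included as well
        starts = [
            (k0, a0, b0, w0, math.log(2.0), s0),    # ω2 = 3
            (k0, a0, b0, w0, math.log(1e-6), s0),   # ω2 ≈ 1: the H0 optimum
            (k0, a0, b0, w0, math.log(9.0), s0),    # ω2 = 10
        ][: max(2, self.restarts)]
        bounds = [_KAPPA_BOUNDS, _LOGIT_BOUNDS, _LOGIT_BOUNDS,
                  (_OMEGA_BOUNDS[0], math.log(1.0)), _OMEGA2_BOUNDS, _SCALE_BOUNDS]
        x, lnl, ok, used, nev = opt.run(starts, bounds)
        return FitResult(lnl, self._xtop(x), ok, used, nev)


class _ResultsBase:
    """Common LRT bookkeeping for the paired H0/H1 fits."""

    def __init__(self, model, h0: FitResult, h1: FitResult,
                 lrt_stat: float, p_value: float):
        self.model = model
        self.h0 = h0
        self.h1 = h1
        self.lrt_stat = lrt_stat
        self.p_value = p_value

    @property
    def lnL0(self) -> float:
        return self.h0.lnL

    @property
    def lnL1(self) -> float:
        return self.h1.lnL

    @property
    def converged(self) -> bool:
        return self.h0.converged and self.h1.converged

    @property
    def significant(self) -> bool:
        """Nominal significance at the χ²₁ 0.05 critical value (3.8415)."""
        return self.lrt_stat > LRT_CRITICAL_05

    def _rows(self):
        raise NotImplementedError

    def summary(self) -> str:
        gene = self.model.aln.gene_id
        lines = [
            f"{self.__class__.__name__} — gene {gene}",
            f"  codons: {self.model.aln.n_codons}  "
            f"site patterns: {self.model.engine.n_patterns}  "
            f"taxa: {self.model.aln.n_taxa}",
            f"  lnL(H0) = {self.lnL0:.4f}   lnL(H1) = {self.lnL1:.4f}",
            f"  LRT = {self.lrt_stat:.4f}   p = {self.p_value:.4g}   "
            f"{'significant' if self.significant else 'n.s.'} at 3.8415",
        ]
        lines += [f"  {name:<12s} {value}" for name, value in self._rows()]
        if not self.converged:
            lines.append("  WARNING: optimizer did not report convergence")
        return "\n".join(lines)


class BranchModelResults(_ResultsBase):
    """Paired branch-model fits with the foreground/background ω contrast."""

    @property
    def omega0(self) -> float:
        return self.h1.params["omega0"]

    @property
    def omega1(self) -> float:
        return self.h1.params["omega1"]

    @property
    def kappa(self) -> float:
        return self.h1.params["kappa"]

    def _rows(self):
        return [
            ("kappa", f"{self.kappa:.4f}"),
            ("omega_bg", f"{self.omega0:.4f}"),
            ("omega_fg", f"{self.omega1:.4f}"),
            ("omega_H0", f"{self.h0.params['omega']:.4f}"),
        ]


class BranchSiteModelResults(_ResultsBase):
    """Paired branch-site model A fits."""

    @property
    def omega0(self) -> float:
        return self.h1.params["omega0"]

    @property
    def omega2(self) -> float:
        return self.h1.params["omega2"]

    @property
    def kappa(self) -> float:
        return self.h1.params["kappa"]

    def _rows(self):
        p = self.h1.params
        rest = max(0.0, 1.0 - p["p0"] - p["p1"])
        return [
            ("kappa", f"{p['kappa']:.4f}"),
            ("omega0", f"{p['omega0']:.4f}"),
            ("omega2", f"{p['omega2']:.4f}"),
            ("p0/p1/p2", f"{p['p0']:.3f}/{p['p1']:.3f}/{rest:.3f}"),
        ]


def fit_branch_model(aln: CodonAlignment, tree: PhyloTree,
                     hypothesis: str | None = None, **config):
    """Functional wrapper over :class:`BranchModel`."""
    return BranchModel(aln, tree, **config).fit(hypothesis)


def fit_branch_site(aln: CodonAlignment, tree: PhyloTree,
                    hypothesis: str | None = None, **config):
    """Functional wrapper over :class:`BranchSiteModel`."""
    return BranchSiteModel(aln, tree, **config).fit(hypothesis)
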