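"""Mass-action kinetics of tip and junction counts.

The network's composition is summarized by n1 (tips) and n3 (junctions).
Each morphological process contributes a signed rate beta_{X,Y} to the net
creation of degree-Y nodes; fusions are second order (they need partners),
while fission, outgrowth, resorption and mitophagy are at most first
order.  With |E| = (n1 + 3 n3)/2 and dispersion fraction alpha (share of
tips on isolated two-node tubules):

* fission:        beta_fis,1 = 2 k_fis |E|
* tip-tip fusion: beta_ttf,1 = -1/2 k_tt [ a n1 (a n1 - 2)
                    + 2 a (1-a) n1^2
                    + 1/2 sum_{v in L(G)} ( 2 (1-a) n1 - 2
                        - sum_{u in N2(v) u N3(v)} (3 - deg u) ) ]
* tip-side fusion: beta_tsf,1 = -k_ts [ a n1 (|E|-1) + (1-a) n1 (|E|-3) ]
                             = -1/2 k_ts n1 [ n1 + 3 n3 + 4 a - 6 ]
* beta_tsf,3 = -beta_tsf,1
* outgrowth:  beta_out,1 = beta_out,3 = k_out |E|
* resorption: beta_res,1 = beta_res,3 = -k_res (1 - a) n1
* mitophagy:  beta_aut,1 = -2 k_aut a

and the node-count ODEs are

    dn1/dt = beta_fis,1 + beta_ttf,1 + beta_tsf,1 + beta_out,1
             + beta_res,1 + beta_aut,1
    dn3/dt = beta_tsf,3 + beta_out,3 + beta_res,3.

At steady state these balance into a single relation between n1 and n3,

    a0 n1 + a1 n3 + a2 = b0 n1^2 + b1 n1 n3 + b2 n1,

whose admissible reductions are a quadratic law n3(n1) (b1 = 0) and a
linear law (b0 = b1 = 0).  :class:`SteadyStateModel` fits both to (n1, n3)
scatter data - the quadratic under its positivity constraint on the
leading coefficient - and selects the linear law whenever the constrained
quadratic fails to converge or its leading coefficient collapses to zero,
which is exactly what happens on linearly generated data.

The tip-tip leaf-neighborhood sum needs the actual graph; the counts-only
(continuum) route evaluates the bracketed leaf term with the neighborhood
correction set to zero (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .graph import MLGraph, canonical_certificate, graph_statistics
from .ops import OP_LABELS, OpLabel, legal_moves

__all__ = [
    "RateModel",
    "BetaRates",
    "beta_rates",
    "beta_rates_counts",
    "ts_fusion_rate_forms",
    "tt_fusion_pair_count",
    "ode_rhs",
    "SteadyStateFit",
    "steady_state_n3",
    "SteadyStateModel",
    "SteadyStateResults",
    "fit_steady_state_models",
    "gillespie_trajectory",
    "TrajectoryPoint",
]


@dataclass(frozen=True)
class RateModel:
    """Per-unit-time rate constants of the morphological processes.

    ``k_flip`` drives vertex flips in stochastic simulation only; flips
    conserve (n1, n3) and therefore never enter the node-count kinetics.
    """

    k_fis: float = 1.0
    k_fus_tt: float = 1.0
    k_fus_ts: float = 1.0
    k_out: float = 1.0
    k_res: float = 1.0
    k_aut: float = 1.0
    k_flip: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_fis", "k_fus_tt", "k_fus_ts", "k_out", "k_res", "k_aut", "k_flip"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def op_rates(self) -> dict[OpLabel, float]:
        return {
            "fission": self.k_fis,
            "tt_fusion": self.k_fus_tt,
            "ts_fusion": self.k_fus_ts,
            "outgrowth": self.k_out,
            "resorption": self.k_res,
            "mitophagy": self.k_aut,
            "vertex_flip": self.k_flip,
        }


@dataclass(frozen=True)
class BetaRates:
    """Signed contribution rates beta_{X,Y} of process X to degree-Y nodes."""

    beta_fis_1: float
    beta_ttf_1: float
    beta_tsf_1: float
    beta_tsf_3: float
    beta_out_1: float
    beta_out_3: float
    beta_res_1: float
    beta_res_3: float
    beta_aut_1: float


def _ttf_leaf_sum(graph: MLGraph, alpha: float, n1: int) -> float:
    """The leaf-neighborhood correction sum of the tip-tip fusion rate."""
    total = 0.0
    for v in graph.leaves():
        nbhd = graph.k_neighborhood(v, 2) | graph.k_neighborhood(v, 3)
        correction = sum(3 - graph.degree(u) for u in nbhd)
        total += 2.0 * (1.0 - alpha) * n1 - 2.0 - correction
    return total


def ts_fusion_rate_forms(graph: MLGraph, k_fus_ts: float) -> tuple[float, float]:
    """Both printed tip-side fusion forms; they agree identically.

    Form 1 counts eligible target edges per tip class (|E|-1 for a tip on
    an isolated tubule, |E|-3 for a tip anchored at a junction); form 2 is
    its closed rearrangement in (n1, n3, alpha).
    """
    s = graph_statistics(graph)
    E, n1, n3, a = s.E, s.n1, s.n3, s.alpha
    form1 = -k_fus_ts * (a * n1 * (E - 1) + (1 - a) * n1 * (E - 3))
    form2 = -0.5 * k_fus_ts * n1 * (n1 + 3 * n3 + 4 * a - 6)
    return form1, form2


def beta_rates(graph: MLGraph, rates: RateModel) -> BetaRates:
    """Process rates evaluated exactly on a graph (leaf sums included)."""
    s = graph_statistics(graph)
    E, n1, n3, a = s.E, s.n1, s.n3, s.alpha
    beta_fis = 2.0 * rates.k_fis * E
    bracket = (
        a * n1 * (a * n1 - 2.0)
        + 2.0 * a * (1.0 - a) * n1**2
        + 0.5 * _ttf_leaf_sum(graph, a, n1)
    )
    beta_ttf = -0.5 * rates.k_fus_tt * bracket
    beta_tsf_1, _ = ts_fusion_rate_forms(graph, rates.k_fus_ts)
    beta_out = rates.k_out * E
    beta_res = -rates.k_res * (1.0 - a) * n1
    beta_aut = -2.0 * rates.k_aut * a
    return BetaRates(
        beta_fis_1=beta_fis,
        beta_ttf_1=beta_ttf,
        beta_tsf_1=beta_tsf_1,
        beta_tsf_3=-beta_tsf_1,
        beta_out_1=beta_out,
        beta_out_3=beta_out,
        beta_res_1=beta_res,
        beta_res_3=beta_res,
        beta_aut_1=beta_aut,
    )


def beta_rates_counts(
    n1: float, n3: float, alpha: float, rates: RateModel
) -> BetaRates:
    """Continuum-limit process rates from (n1, n3, alpha) alone.

    Identical to :func:`beta_rates` except that the tip-tip leaf sum's
    neighborhood correction (which needs the actual graph) is zero.
    """
    E = (n1 + 3.0 * n3) / 2.0
    a = alpha
    beta_fis = 2.0 * rates.k_fis * E
    leaf_sum = n1 * (2.0 * (1.0 - a) * n1 - 2.0)
    bracket = a * n1 * (a * n1 - 2.0) + 2.0 * a * (1.0 - a) * n1**2 + 0.5 * leaf_sum
    beta_ttf = -0.5 * rates.k_fus_tt * bracket
    beta_tsf_1 = -0.5 * rates.k_fus_ts * n1 * (n1 + 3.0 * n3 + 4.0 * a - 6.0)
    beta_out = rates.k_out * E
    beta_res = -rates.k_res * (1.0 - a) * n1
    beta_aut = -2.0 * rates.k_aut * a
    return BetaRates(
        beta_fis_1=beta_fis,
        beta_ttf_1=beta_ttf,
        beta_tsf_1=beta_tsf_1,
        beta_tsf_3=-beta_tsf_1,
        beta_out_1=beta_out,
        beta_out_3=beta_out,
        beta_res_1=beta_res,
        beta_res_3=beta_res,
        beta_aut_1=beta_aut,
    )


def tt_fusion_pair_count(graph: MLGraph) -> int:
    """Brute-force count of legal unordered tip-pair fusions (diagnostic).

    The printed tip-tip rate uses mean-field pair counting with a
    neighborhood correction; this exact count lets the two be compared
    (see docs/methods.md) without silently altering the printed form.
    """
    from .ops import tt_fusion

    tips = graph.leaves()
    count = 0
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            if tt_fusion(graph, tips[i], tips[j]).applied:
                count += 1
    return count


def ode_rhs(
    graph_or_counts: MLGraph | tuple[float, float],
    rates: RateModel,
    alpha: float | None = None,
) -> tuple[float, float]:
    """(dn1/dt, dn3/dt): the node-count ODE right-hand side.

    Pass a graph for exact structural evaluation, or (n1, n3) with a
    supplied ``alpha`` for the continuum route.
    """
    if isinstance(graph_or_counts, MLGraph):
        b = beta_rates(graph_or_counts, rates)
    else:
        n1, n3 = graph_or_counts
        if alpha is None:
            raise ValueError("continuum evaluation requires alpha")
        b = beta_rates_counts(n1, n3, alpha, rates)
    dn1 = (
        b.beta_fis_1
        + b.beta_ttf_1
        + b.beta_tsf_1
        + b.beta_out_1
        + b.beta_res_1
        + b.beta_aut_1
    )
    dn3 = b.beta_tsf_3 + b.beta_out_3 + b.beta_res_3
    return dn1, dn3


# -- steady-state relation and model fitting ------------------------------


@dataclass(frozen=True)
class SteadyStateFit:
    """Fitted steady-state relation between n1 and n3.

    The regression identifies only the polynomial n3(n1); the mass-action
    parameters (a_i, b_j) are a gauge.  We normalize a1 = 1, a0 = 0, so
    b0 = quadratic coefficient, b2 = slope, a2 = -intercept, b1 = 0.
    """

    a0: float
    a1: float
    a2: float
    b0: float
    b1: float
    b2: float
    model: Literal["linear", "quadratic"]
    r_squared: float
    pvalues: dict[str, float] = field(default_factory=dict)
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True

    @classmethod
    def from_polynomial(
        cls,
        model: Literal["linear", "quadratic"],
        quadratic: float,
        slope: float,
        intercept: float,
        **kw,
    ) -> "SteadyStateFit":
        if model == "linear" and quadratic != 0.0:
            raise ValueError("linear model requires a zero quadratic coefficient")
        return cls(
            a0=0.0,
            a1=1.0,
            a2=-intercept,
            b0=quadratic,
            b1=0.0,
            b2=slope,
            model=model,
            **kw,
        )

    @property
    def quadratic_coef(self) -> float:
        return self.b0 / self.a1

    @property
    def slope(self) -> float:
        return (self.b2 - self.a0) / self.a1

    @property
    def intercept(self) -> float:
        return -self.a2 / self.a1


def steady_state_n3(n1: float, fit: SteadyStateFit, general: bool = False) -> float:
    """Evaluate n3(n1) under the fitted steady-state relation.

    ``general=True`` evaluates the unreduced rational form
    n3 = (-b0 n1^2 + (a0 - b2) n1 + a2) / (b1 n1 - a1), raising at the
    pole b1 n1 = a1; otherwise the reduction matching ``fit.model`` is
    used (quadratic when b1 = 0, linear when additionally b0 = 0).
    """
    if general:
        denom = fit.b1 * n1 - fit.a1
        if denom == 0:
            raise ZeroDivisionError("pole: b1 * n1 equals a1")
        return (-fit.b0 * n1**2 + (fit.a0 - fit.b2) * n1 + fit.a2) / denom
    if fit.model == "quadratic":
        return fit.quadratic_coef * n1**2 + fit.slope * n1 + fit.intercept
    return fit.slope * n1 + fit.intercept


#: relative tolerance below which the constrained quadratic coefficient is
#: considered to have collapsed to zero
QUADRATIC_COLLAPSE_RTOL = 1e-8


class SteadyStateModel:
    """Steady-state n3-vs-n1 regression with model selection.

    Fits the linear law by ordinary least squares and the quadratic law by
    bound-constrained least squares (leading coefficient >= 0, the
    positive-scaling regime).  ``fit()`` returns a
    :class:`SteadyStateResults`; the quadratic is selected only when its
    constrained fit converges with a genuinely nonzero leading
    coefficient, mirroring the collapse of that coefficient on linearly
    generated data.
    """

    def __init__(self, n1: Sequence[float], n3: Sequence[float]) -> None:
        n1 = np.asarray(n1, dtype=float)
        n3 = np.asarray(n3, dtype=float)
        if n1.shape != n3.shape or n1.ndim != 1:
            raise ValueError("n1 and n3 must be equal-length 1-d sequences")
        if len(n1) < 3:
            raise ValueError("at least 3 points required")
        if (n1 < 0).any() or (n3 < 0).any():
            raise ValueError("n1 and n3 must be non-negative")
        if np.ptp(n1) == 0:
            raise ValueError("degenerate design: all n1 equal")
        self.n1 = n1
        self.n3 = n3

    @classmethod
    def from_dataframe(cls, df, n1_col: str = "n1", n3_col: str = "n3") -> "SteadyStateModel":
        return cls(df[n1_col].to_numpy(), df[n3_col].to_numpy())

    #: one-sided z threshold for the quadratic coefficient to count as
    #: genuinely positive rather than boundary noise
    Z_POSITIVE = 2.0

    def fit(
        self, collapse_rtol: float = QUADRATIC_COLLAPSE_RTOL
    ) -> "SteadyStateResults":
        import statsmodels.api as sm

        x, y = self.n1, self.n3

        X_lin = sm.add_constant(x)
        ols_lin = sm.OLS(y, X_lin).fit()
        lin_intercept, lin_slope = ols_lin.params
        lin_ci = ols_lin.conf_int(alpha=0.05)

        # constrained quadratic y ~ q2 x^2 + q1 x + q0 with q2 >= 0: a
        # single bound constraint, so the KKT solution is exact - take the
        # unconstrained OLS optimum if its leading coefficient is already
        # non-negative, else pin q2 = 0 (which is the linear fit)
        X_quad = np.column_stack([np.ones_like(x), x, x**2])
        ols_quad = sm.OLS(y, X_quad).fit()
        q0u, q1u, q2u = ols_quad.params
        se_q2 = float(ols_quad.bse[2])
        if q2u >= 0:
            q2, q1, q0 = float(q2u), float(q1u), float(q0u)
        else:
            q2, q1, q0 = 0.0, float(lin_slope), float(lin_intercept)
        scale = max(float(np.abs(y).max()), 1e-12)
        q2_rel = abs(q2) * float(x.max()) ** 2 / scale
        quad_converged = True  # closed-form KKT solution
        # the coefficient collapses when the constraint is active, when its
        # magnitude is numerically negligible, or when it is not
        # significantly positive (boundary noise under linear truth)
        quad_collapsed = bool(
            q2_rel < collapse_rtol
            or (se_q2 > 0 and q2u <= self.Z_POSITIVE * se_q2)
            or q2 == 0.0
        )

        if quad_collapsed:
            fit = SteadyStateFit.from_polynomial(
                "linear",
                0.0,
                float(lin_slope),
                float(lin_intercept),
                r_squared=float(ols_lin.rsquared),
                pvalues={
                    "slope": float(ols_lin.pvalues[1]),
                    "intercept": float(ols_lin.pvalues[0]),
                },
                conf_int={
                    "slope": (float(lin_ci[1][0]), float(lin_ci[1][1])),
                    "intercept": (float(lin_ci[0][0]), float(lin_ci[0][1])),
                },
                converged=True,
            )
        else:
            # selected quadratic coincides with unconstrained OLS: use its
            # inference directly
            ci = ols_quad.conf_int(alpha=0.05)
            r2 = float(ols_quad.rsquared)
            fit = SteadyStateFit.from_polynomial(
                "quadratic",
                float(q2),
                float(q1),
                float(q0),
                r_squared=r2,
                pvalues={
                    "quadratic": float(ols_quad.pvalues[2]),
                    "slope": float(ols_quad.pvalues[1]),
                    "intercept": float(ols_quad.pvalues[0]),
                },
                conf_int={
                    "quadratic": (float(ci[2][0]), float(ci[2][1])),
                    "slope": (float(ci[1][0]), float(ci[1][1])),
                    "intercept": (float(ci[0][0]), float(ci[0][1])),
                },
                converged=quad_converged,
            )
        return SteadyStateResults(
            fit=fit,
            n_obs=len(x),
            quadratic_coefficient_raw=float(q2),
            quadratic_collapsed=quad_collapsed,
            linear_r_squared=float(ols_lin.rsquared),
        )


@dataclass(frozen=True)
class SteadyStateResults:
    fit: SteadyStateFit
    n_obs: int
    quadratic_coefficient_raw: float
    quadratic_collapsed: bool
    linear_r_squared: float

    @property
    def model(self) -> str:
        return self.fit.model

    def predict(self, n1) -> np.ndarray:
        n1 = np.asarray(n1, dtype=float)
        return np.array([steady_state_n3(v, self.fit) for v in n1])

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Steady-state n3 ~ n1 regression",
            "=" * 40,
            f"selected model:      {f.model}",
            f"observations:        {self.n_obs}",
            f"R-squared:           {f.r_squared:.4f}",
            f"slope:               {f.slope:.6g}",
            f"intercept:           {f.intercept:.6g}",
        ]
        if f.model == "quadratic":
            lines.append(f"quadratic coef:      {f.quadratic_coef:.6g}")
        else:
            lines.append(
                "quadratic coef:      collapsed to "
                f"{self.quadratic_coefficient_raw:.3g} (rejected)"
            )
        for name, p in f.pvalues.items():
            lo, hi = f.conf_int[name]
            lines.append(f"{name:>10s}: p = {p:.3g}, 95% CI [{lo:.4g}, {hi:.4g}]")
        return "\n".join(lines)


def fit_steady_state_models(
    data: Sequence[tuple[float, float]],
    collapse_rtol: float = QUADRATIC_COLLAPSE_RTOL,
) -> SteadyStateResults:
    """Functional wrapper: fit and select from (n1, n3) pairs."""
    arr = np.asarray(list(data), dtype=float)
    return SteadyStateModel(arr[:, 0], arr[:, 1]).fit(collapse_rtol=collapse_rtol)


# -- stochastic simulation ------------------------------------------------


@dataclass(frozen=True)
class TrajectoryPoint:
    time: float
    certificate: str
    n1: int
    n3: int


def gillespie_trajectory(
    seed: MLGraph,
    rates: RateModel,
    t_max: float,
    seed_rng: int,
    max_nodes: int | None = None,
    max_events: int = 100_000,
) -> tuple[list[TrajectoryPoint], MLGraph, bool]:
    """Exact stochastic simulation of the morphological jump process.

    Each legal application of an operation is an independent reaction
    channel with propensity equal to its rate constant; waiting times are
    exponential in the total propensity.  ``max_nodes`` (optional) drops
    channels whose product would exceed the bound, keeping long runs
    tractable.  Returns (trajectory, final graph, absorbed) where
    ``absorbed`` flags early termination in a state with no legal moves.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed_rng)
    op_rates = rates.op_rates()
    active_ops = tuple(op for op in OP_LABELS if op_rates[op] > 0)
    g = seed.copy()
    t = 0.0
    s = graph_statistics(g)
    traj = [TrajectoryPoint(0.0, canonical_certificate(g), s.n1, s.n3)]
    absorbed = False
    for _ in range(max_events):
        moves = legal_moves(g, active_ops)
        if max_nodes is not None:
            moves = [m for m in moves if m.result.n_nodes <= max_nodes]
        props = np.array([op_rates[m.op_label] for m in moves], dtype=float)
        total = props.sum()
        if total <= 0 or not moves:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        choice = rng.choice(len(moves), p=props / total)
        g = moves[choice].result
        s = graph_statistics(g)
        traj.append(TrajectoryPoint(t, canonical_certificate(g), s.n1, s.n3))
    return traj, g, absorbed
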