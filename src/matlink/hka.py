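"""Multilocus HKA (Hudson-Kreitman-Aguade) test.

Contrasts within-taxon polymorphism with between-taxon divergence across
loci. Under neutrality all loci share a divergence time T and a ratio f
of taxon-B to taxon-A effective size, differing only in their mutation
parameter theta_i (= 4 N_A mu_i per locus). Observed counts are compared
with model expectations by a goodness-of-fit statistic

    x2 = sum over loci of
         (S_a - E[S_a])^2/Var[S_a] + (S_b - E[S_b])^2/Var[S_b]
         + (d - E[d])^2/Var[d]

with E[S_a] = theta a1(n_a),        Var[S_a] = E[S_a] + theta^2 a2(n_a)
     E[S_b] = f theta a1(n_b),      Var[S_b] = E[S_b] + (f theta)^2 a2(n_b)
     E[d]   = theta (T + (1+f)/2),  Var[d]   = E[d] + (theta (1+f)/2)^2

(time in units of 2 N_A generations; the (1+f)/2 term is the expected
coalescence time of one lineage per taxon in the ancestor). Significance
comes from a parametric bootstrap: neutral coalescent replicates are
simulated at the fitted parameters, refitted, and the p-value is the
fraction of simulated x2 at or above the observed one. Loci are assumed
non-recombining internally and freely recombining from one another.

Two fitters are provided. ``method='moment'`` solves the classical HKA
moment equations by fixed-point iteration (vectorised over simulation
replicates, so the bootstrap refits stay cheap); ``method='minimize'``
polishes the full x2 objective numerically from the moment start. The
test uses one method consistently for the observed data and every null
replicate, which is what keeps the bootstrap calibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .diversity import neutrality_constants

_THETA_FLOOR = 1e-9


class HKAError(ValueError):
    pass


@dataclass
class HKALocusData:
    """Observed counts for one locus: sample sizes, segregating sites
    within each taxon, and mean pairwise between-taxon differences.
    ``n_b = 0`` omits the B-polymorphism term (one-taxon HKA)."""

    locus: str
    n_a: int
    n_b: int
    S_a: int
    S_b: int
    d_ab: float
    L_valid: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 2:
            raise HKAError(f"{self.locus}: need n_a >= 2")
        if self.n_b not in (0,) and self.n_b < 2:
            raise HKAError(f"{self.locus}: n_b must be 0 or >= 2")
        if min(self.S_a, self.S_b) < 0 or self.d_ab < 0:
            raise HKAError(f"{self.locus}: negative counts")
        if self.n_b == 0 and self.S_b != 0:
            raise HKAError(f"{self.locus}: S_b must be 0 when n_b = 0")


@dataclass
class HKAFit:
    theta_per_locus: dict[str, float]
    T: float
    f: float
    x2_obs: float
    p_value: float | None = None
    n_sims: int = 0
    seed: int | None = None
    method: str = "moment"
    x2_null: np.ndarray | None = field(default=None, repr=False)


def _a_constants(n: int) -> tuple[float, float]:
    if n == 0:
        return 0.0, 0.0
    c = neutrality_constants(n)
    return c.a1, c.a2


def hka_expectations(
    theta: float, T: float, f: float, n_a: int, n_b: int
) -> dict[str, float]:
    """Model expectations and variances for one locus."""
    a1a, a2a = _a_constants(n_a)
    a1b, a2b = _a_constants(n_b)
    out = {
        "E_S_a": theta * a1a,
        "Var_S_a": theta * a1a + theta**2 * a2a,
        "E_S_b": f * theta * a1b,
        "Var_S_b": f * theta * a1b + (f * theta) ** 2 * a2b,
        "E_d": theta * (T + (1 + f) / 2.0),
        "Var_d": theta * (T + (1 + f) / 2.0) + (theta * (1 + f) / 2.0) ** 2,
    }
    return out


def _shape_arrays(data: list[HKALocusData]):
    a1a = np.array([_a_constants(d.n_a)[0] for d in data])
    a2a = np.array([_a_constants(d.n_a)[1] for d in data])
    a1b = np.array([_a_constants(d.n_b)[0] for d in data])
    a2b = np.array([_a_constants(d.n_b)[1] for d in data])
    has_b = np.array([d.n_b >= 2 for d in data])
    return a1a, a2a, a1b, a2b, has_b


def _x2_batch(Sa, Sb, d, theta, T, f, a1a, a2a, a1b, a2b, has_b):
    """x2 for batched data/params. theta: (..., L); T, f: (...,)."""
    theta = np.maximum(theta, _THETA_FLOOR)
    T = np.maximum(T, 0.0)[..., None]
    f = np.maximum(f, _THETA_FLOOR)[..., None]
    C = T + (1 + f) / 2.0
    ESa = theta * a1a
    VSa = ESa + theta**2 * a2a
    ESb = f * theta * a1b
    VSb = ESb + (f * theta) ** 2 * a2b
    Ed = theta * C
    Vd = Ed + (theta * (1 + f) / 2.0) ** 2
    x2 = (Sa - ESa) ** 2 / VSa + (d - Ed) ** 2 / Vd
    if has_b.any():
        x2 = x2 + np.where(has_b, (Sb - ESb) ** 2 / np.maximum(VSb, _THETA_FLOOR), 0.0)
    return x2.sum(axis=-1)


def _moment_fit_batch(Sa, Sb, d, a1a, a2a, a1b, a2b, has_b, n_iter: int = 200):
    """Fixed-point solution of the HKA moment equations, batched.

    Per locus: S_a + S_b + d = theta [a1(n_a) + f a1(n_b) + T + (1+f)/2];
    globally: sum S_b = f sum theta a1(n_b) and
              sum d  = (T + (1+f)/2) sum theta.
    f is fixed at 1 when no locus has B-taxon polymorphism data.
    """
    Sa = np.asarray(Sa, float)
    Sb = np.asarray(Sb, float)
    d = np.asarray(d, float)
    batch = Sa.shape[:-1]
    total = Sa + Sb + d
    fit_f = bool(has_b.any())
    f = np.ones(batch)
    T = np.maximum(d.mean(axis=-1) / np.maximum(Sa.mean(axis=-1) / a1a.mean(), _THETA_FLOOR), 0.1)
    theta = np.maximum(Sa / a1a, _THETA_FLOOR)
    a1b_eff = np.where(has_b, a1b, 0.0)
    for _ in range(n_iter):
        C = T[..., None] + (1 + f[..., None]) / 2.0
        denom = a1a + f[..., None] * a1b_eff + C
        theta = np.maximum(total / denom, _THETA_FLOOR)
        sum_theta = theta.sum(axis=-1)
        if fit_f:
            denom_f = (theta * a1b_eff).sum(axis=-1)
            f = np.where(
                denom_f > 0, Sb.sum(axis=-1) / np.maximum(denom_f, _THETA_FLOOR), 1.0
            )
            f = np.clip(f, 1e-4, 1e4)
        T = np.maximum(d.sum(axis=-1) / np.maximum(sum_theta, _THETA_FLOOR) - (1 + f) / 2.0, 0.0)
    x2 = _x2_batch(Sa, Sb, d, theta, T, f, a1a, a2a, a1b, a2b, has_b)
    return theta, T, f, x2


def _minimize_fit(Sa, Sb, d, a1a, a2a, a1b, a2b, has_b):
    """Numerical minimisation of the full x2 from the moment start."""
    L = len(Sa)
    th0, T0, f0, _ = _moment_fit_batch(
        np.asarray(Sa)[None, :], np.asarray(Sb)[None, :], np.asarray(d)[None, :],
        a1a, a2a, a1b, a2b, has_b,
    )
    th0, T0, f0 = th0[0], T0, f0
    fit_f = bool(has_b.any())

    def objective(params):
        theta = np.exp(params[:L])
        T = params[L]
        f = np.exp(params[L + 1]) if fit_f else 1.0
        return _x2_batch(
            Sa, Sb, d, theta, np.atleast_1d(T), np.atleast_1d(f),
            a1a, a2a, a1b, a2b, has_b,
        )[0]

    x0 = np.concatenate([np.log(np.maximum(th0, 1e-6)), [max(T0[0], 1e-3)]])
    if fit_f:
        x0 = np.concatenate([x0, [np.log(max(f0[0], 1e-4))]])
    bounds = [(-20, 20)] * L + [(0, 1e4)] + ([(-9, 9)] if fit_f else [])
    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
    theta = np.exp(res.x[:L])
    T = res.x[L]
    f = float(np.exp(res.x[L + 1])) if fit_f else 1.0
    return theta[None, :], np.atleast_1d(T), np.atleast_1d(f), np.atleast_1d(res.fun)


def fit_hka(data: list[HKALocusData], method: str = "moment") -> HKAFit:
    """Point estimates (theta per locus, T, f) and the observed x2."""
    if len(data) < 2:
        raise HKAError("HKA needs >= 2 loci")
    Sa = np.array([d.S_a for d in data], float)
    Sb = np.array([d.S_b for d in data], float)
    dd = np.array([d.d_ab for d in data], float)
    if (Sa + Sb + dd <= 0).all():
        raise HKAError("degenerate data: no variation at any locus")
    shapes = _shape_arrays(data)
    if method == "moment":
        theta, T, f, x2 = _moment_fit_batch(Sa[None, :], Sb[None, :], dd[None, :], *shapes)
    elif method == "minimize":
        theta, T, f, x2 = _minimize_fit(Sa, Sb, dd, *shapes)
    else:
        raise ValueError(f"unknown method {method!r}")
    return HKAFit(
        theta_per_locus={d.locus: float(t) for d, t in zip(data, theta[0])},
        T=float(T[0]),
        f=float(f[0]),
        x2_obs=float(x2[0]),
        method=method,
    )


# ---------------------------------------------------------------------------
# Coalescent null simulation
# ---------------------------------------------------------------------------


def _simulate_S(rng: np.random.Generator, n: int, theta, n_sims: int) -> np.ndarray:
    """Neutral-coalescent segregating sites for a sample of size n.

    Total tree length = sum_{i=2..n} i * t_i with t_i ~ Exp(rate i(i-1)/2)
    in units of 2N generations; S ~ Poisson(theta/2 * length), giving
    E[S] = theta a1(n) and Var[S] = E[S] + theta^2 a2(n).
    """
    theta = np.broadcast_to(np.asarray(theta, float), (n_sims,))
    length = np.zeros(n_sims)
    for i in range(2, n + 1):
        length += i * rng.exponential(2.0 / (i * (i - 1)), size=n_sims)
    return rng.poisson(theta / 2.0 * length).astype(float)


def hka_null_simulate(
    fit: HKAFit,
    data: list[HKALocusData],
    n_sims: int,
    rng: np.random.Generator,
    method: str = "moment",
) -> np.ndarray:
    """Empirical null x2 distribution at the fitted parameters.

    Per replicate and locus: S_a from the taxon-A coalescent at theta_i,
    S_b from the taxon-B coalescent at f*theta_i, and divergence d as a
    Poisson count with mean theta_i*(T + t_anc), where t_anc ~ Exp(mean
    (1+f)/2) is the ancestral coalescence of the two sampled lineages.
    Each replicate is refitted before its x2 is recorded.
    """
    if n_sims < 1:
        raise HKAError("n_sims must be >= 1")
    L = len(data)
    thetas = np.array([fit.theta_per_locus[d.locus] for d in data])
    Sa = np.empty((n_sims, L))
    Sb = np.zeros((n_sims, L))
    dd = np.empty((n_sims, L))
    for j, d in enumerate(data):
        Sa[:, j] = _simulate_S(rng, d.n_a, thetas[j], n_sims)
        if d.n_b >= 2:
            Sb[:, j] = _simulate_S(rng, d.n_b, fit.f * thetas[j], n_sims)
        t_anc = rng.exponential((1 + fit.f) / 2.0, size=n_sims)
        dd[:, j] = rng.poisson(thetas[j] * (fit.T + t_anc))
    shapes = _shape_arrays(data)
    if method == "moment":
        _, _, _, x2 = _moment_fit_batch(Sa, Sb, dd, *shapes)
    else:
        x2 = np.array(
            [_minimize_fit(Sa[i], Sb[i], dd[i], *shapes)[3][0] for i in range(n_sims)]
        )
    return x2


def hka_test(
    data: list[HKALocusData],
    n_sims: int = 1000,
    seed: int | None = None,
    method: str = "moment",
) -> HKAFit:
    """Full HKA test: fit, simulate the null, report p = P(x2_sim >= x2_obs)."""
    fit = fit_hka(data, method=method)
    rng = np.random.default_rng(seed)
    x2_null = hka_null_simulate(fit, data, n_sims, rng, method=method)
    fit.p_value = float(np.mean(x2_null >= fit.x2_obs))
    fit.n_sims = n_sims
    fit.seed = seed
    fit.x2_null = x2_null
    return fit


def hka_data_from_alignments(locus, aln_a, aln_b) -> HKALocusData:
    """Observed HKA counts from two taxon alignments of one locus.

    S within each taxon and the mean pairwise between-taxon difference
    count are all scored on the complete-deletion columns of the combined
    alignment, so polymorphism and divergence see the same sites.
    """
    from .alignment import Alignment, complete_deletion_columns

    combined = Alignment(locus, list(aln_a.members) + list(aln_b.members))
    valid = complete_deletion_columns(combined)
    if len(valid) == 0:
        raise HKAError(f"{locus}: no analysable sites after complete deletion")
    mat = combined.to_matrix()[:, valid]
    na, nb = aln_a.n, aln_b.n

    def seg(sub: np.ndarray) -> int:
        return int(
            sum(len(np.unique(sub[:, j])) > 1 for j in range(sub.shape[1]))
        )

    S_a = seg(mat[:na])
    S_b = seg(mat[na:]) if nb >= 2 else 0
    diffs = 0.0
    for i in range(na):
        diffs += (mat[i][None, :] != mat[na:]).sum()
    d_ab = float(diffs / (na * nb)) if nb else 0.0
    return HKALocusData(
        locus=locus, n_a=na, n_b=nb if nb >= 2 else 0,
        S_a=S_a, S_b=S_b, d_ab=d_ab, L_valid=len(valid),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

HKA_TSV_COLUMNS = ["locus", "n_a", "n_b", "S_a", "S_b", "d_ab", "L_valid"]


def read_hka_tsv(path: str | Path) -> list[HKALocusData]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in HKA_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        HKALocusData(
            locus=str(r.locus), n_a=int(r.n_a), n_b=int(r.n_b),
            S_a=int(r.S_a), S_b=int(r.S_b), d_ab=float(r.d_ab),
            L_valid=int(r.L_valid),
        )
        for r in df.itertuples()
    ]


def write_hka_report(fit: HKAFit, data: list[HKALocusData], path: str | Path) -> None:
    path = Path(path)
    report = {
        "theta_per_locus": fit.theta_per_locus,
        "T": fit.T,
        "f": fit.f,
        "x2_obs": fit.x2_obs,
        "p_value": fit.p_value,
        "n_sims": fit.n_sims,
        "seed": fit.seed,
        "method": fit.method,
        "loci": [
            {
                "locus": d.locus, "n_a": d.n_a, "n_b": d.n_b,
                "S_a": d.S_a, "S_b": d.S_b, "d_ab": d.d_ab,
                "expectations": hka_expectations(
                    fit.theta_per_locus[d.locus], fit.T, fit.f, d.n_a, d.n_b
                ),
            }
            for d in data
        ],
    }
    path.write_text(json.dumps(report, indent=2) + "\n")
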