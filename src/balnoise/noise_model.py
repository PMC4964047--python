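"""Equilibrium model of transcriptional noise in homozygotes vs heterozygotes.

The model couples a two-stage (mRNA -> protein) birth-death gene to an
equilibrium promoter whose occupancy depends on the level of a single
transcription factor.  With RNA-polymerase level ``R`` (scaled by the
polymerase-DNA dissociation constant K1), TF level ``T`` (scaled by the
TF-DNA dissociation constant K2) and cooperativity ``s = K1/K3``
(activator s > 1, repressor s < 1), the normalized transcription rate is

    f(T) = R (1 + s T) / (1 + R + (1 + s R) T)
         = f(0) * (1 + (phi - 1) / (1 + tau / T)),

with tau = (1 + R)/(1 + s R), fold change phi = (R + 1)/(R + 1/s) and
basal level f(0) = R/(1 + R).

A heterozygote whose two alleles bind the TF with dissociation constants
K2 and lambda*K2 transcribes at g_lambda(T) = [f(T) + f(T/lambda)] / 2.
The mean-matched homozygote carries lambda_bar*K2 on both alleles, with
lambda_bar solving <f(T/lambda_bar)> = <g_lambda(T)> over the cell
ensemble, in which T is gamma-distributed, T ~ Gamma(a, b).

The stationary protein noise decomposes additively into an intrinsic
birth-death term 1/<p>, an mRNA-propagation term (1/<m>)/(1 + gm/gp),
the mRNA Poisson term 1/<m>, and the extrinsic term
eta_g^2 = Var(g)/<g>^2 carrying the allele-dependent TF-binding
variation.  Mean matching cancels every term except eta_g^2, so the
noise difference

    delta_eta2 = eta_p^2[f_lambda_bar] - eta_p^2[g_lambda]

isolates the extrinsic-noise buffering conferred by heterozygosity:
averaging two differently-scaled copies of f flattens the response to
TF fluctuations, hence delta_eta2 >= 0, with equality at lambda = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "NoiseModelParams",
    "RateFunction",
    "NoiseDecomposition",
    "DeltaEtaResult",
    "rate_f",
    "ensemble_mean_rate",
    "ensemble_stats",
    "match_mean",
    "noise_decomposition",
    "delta_eta2",
]

# Gauss-Legendre nodes on (0, 1); the gamma ensemble average is computed
# as an integral over the probability transform u -> Gamma.ppf(u), which
# is smooth and bounded for the bounded integrands used here (f <= 1).
_GL_ORDER = 600
_gl_x, _gl_w = np.polynomial.legendre.leggauss(_GL_ORDER)
_GL_U = 0.5 * (_gl_x + 1.0)
_GL_W = 0.5 * _gl_w


@dataclass(frozen=True)
class NoiseModelParams:
    """Biochemical parameters of the promoter/expression model.

    Rates are in units of the mRNA decay rate unless stated otherwise.
    Defaults put the gene in the highly-expressed regime where extrinsic
    noise dominates, which is the regime of interest for noise buffering.

    alpha_m : transcription rate scale (mRNA per unit time at f = 1)
    alpha_p : translation rate per mRNA
    gamma_m : mRNA decay rate
    gamma_p : protein decay rate
    R       : [RNA polymerase]/K1
    s       : K1/K3; > 1 activator, < 1 repressor
    lam     : allele discrepancy factor on K2 (heterozygote: K2, lam*K2)
    a, b    : gamma shape/scale of the K2-scaled TF level T
    """

    alpha_m: float = 200.0
    alpha_p: float = 10.0
    gamma_m: float = 1.0
    gamma_p: float = 0.1
    R: float = 1.0
    s: float = 4.0
    lam: float = 1.0
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_m", "alpha_p", "gamma_m", "gamma_p", "R", "s", "lam", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "NoiseModelParams":
        return replace(self, **kw)


class RateFunction:
    """The promoter-occupancy rate f(T) with its derived constants."""

    def __init__(self, R: float, s: float):
        if R <= 0 or s <= 0:
            raise ValueError("R and s must be positive")
        self.R = R
        self.s = s
        self.tau = (1.0 + R) / (1.0 + s * R)
        self.f0 = R / (1.0 + R)
        self.phi = (R + 1.0) / (R + 1.0 / s)

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        R, s = self.R, self.s
        return R * (1.0 + s * T) / (1.0 + R + (1.0 + s * R) * T)

    def factored(self, T):
        """The equivalent f(0)*(1 + (phi-1)/(1 + tau/T)) form."""
        T = np.asarray(T, dtype=float)
        return self.f0 * (1.0 + (self.phi - 1.0) / (1.0 + self.tau / T))

    def g(self, T, lam: float):
        """Heterozygote rate g_lambda(T) = [f(T) + f(T/lam)] / 2."""
        return 0.5 * (self(T) + self(np.asarray(T, dtype=float) / lam))


def rate_f(params: NoiseModelParams) -> RateFunction:
    return RateFunction(params.R, params.s)


def _gamma_nodes(a: float, b: float) -> np.ndarray:
    return stats.gamma.ppf(_GL_U, a, scale=b)


def ensemble_stats(func, a: float, b: float) -> tuple[float, float]:
    """(mean, variance) of func(T) for T ~ Gamma(a, b) by quadrature."""
    if a <= 0 or b <= 0:
        raise ValueError("gamma parameters must be positive")
    vals = func(_gamma_nodes(a, b))
    mean = float(np.sum(_GL_W * vals))
    var = float(np.sum(_GL_W * (vals - mean) ** 2))
    return mean, var


def ensemble_mean_rate(
    rate: RateFunction, lam: float, a: float, b: float, mode: str = "het"
) -> float:
    """<g_lambda(T)> (mode='het') or <f(T/lam)> (mode='hom') over T ~ Gamma(a, b)."""
    if mode == "het":
        return ensemble_stats(lambda T: rate.g(T, lam), a, b)[0]
    if mode == "hom":
        return ensemble_stats(lambda T: rate(T / lam), a, b)[0]
    raise ValueError("mode must be 'het' or 'hom'")


def match_mean(rate: RateFunction, lam: float, a: float, b: float) -> float:
    """Solve <f(T/lam_bar)> = <g_lambda(T)> for the homozygote factor lam_bar.

    The map lam_bar -> <f(T/lam_bar)> is strictly monotone (decreasing
    for an activator, increasing for a repressor), so the root is found
    by bracketed bisection on an expanding bracket.
    """
    target = ensemble_mean_rate(rate, lam, a, b, mode="het")

    def resid(lb: float) -> float:
        return ensemble_mean_rate(rate, lb, a, b, mode="hom") - target

    lo = min(1.0, lam) / 10.0
    hi = max(1.0, lam) * 10.0
    r_lo, r_hi = resid(lo), resid(hi)
    widen = 0
    while r_lo * r_hi > 0 and widen < 6:
        lo /= 10.0
        hi *= 10.0
        r_lo, r_hi = resid(lo), resid(hi)
        widen += 1
    if r_lo * r_hi > 0:
        raise RuntimeError("mean-matching root not bracketed")
    lam_bar = optimize.brentq(resid, lo, hi, xtol=1e-14, rtol=1e-14)
    if abs(resid(lam_bar)) > 1e-10:
        raise RuntimeError("mean-matching residual above tolerance")
    return float(lam_bar)


@dataclass
class NoiseDecomposition:
    mean_g: float
    mean_m: float
    mean_p: float
    eta2_intrinsic: float
    eta2_mrna_propagation: float
    eta2_mrna_poisson: float
    eta2_g: float

    @property
    def eta2_total(self) -> float:
        return (
            self.eta2_intrinsic
            + self.eta2_mrna_propagation
            + self.eta2_mrna_poisson
            + self.eta2_g
        )

    @property
    def eta2_m(self) -> float:
        """mRNA noise level: 1/<m> + eta_g^2."""
        return self.eta2_mrna_poisson + self.eta2_g


def noise_decomposition(
    params: NoiseModelParams, mode: str = "het", lam: float | None = None
) -> NoiseDecomposition:
    """Stationary protein-noise decomposition for one genotype.

    mode='het' uses g_lambda; mode='hom' uses f(T/lam) with lam usually
    the mean-matched lambda_bar.  The total is

        eta_p^2 = 1/<p> + (1/<m>)/(1 + gm/gp) + 1/<m> + eta_g^2
    """
    if lam is None:
        lam = params.lam
    rate = rate_f(params)
    if mode == "het":
        mean_g, var_g = ensemble_stats(lambda T: rate.g(T, lam), params.a, params.b)
    elif mode == "hom":
        mean_g, var_g = ensemble_stats(lambda T: rate(T / lam), params.a, params.b)
    else:
        raise ValueError("mode must be 'het' or 'hom'")
    if mean_g <= 0:
        raise ValueError("mean transcription rate must be positive")
    mean_m = params.alpha_m / params.gamma_m * mean_g
    mean_p = params.alpha_p / params.gamma_p * mean_m
    return NoiseDecomposition(
        mean_g=mean_g,
        mean_m=mean_m,
        mean_p=mean_p,
        eta2_intrinsic=1.0 / mean_p,
        eta2_mrna_propagation=(1.0 / mean_m) / (1.0 + params.gamma_m / params.gamma_p),
        eta2_mrna_poisson=1.0 / mean_m,
        eta2_g=var_g / mean_g**2,
    )


@dataclass
class DeltaEtaResult:
    lam: float
    a: float
    lam_bar: float
    eta2_het: float
    eta2_hom: float

    @property
    def delta_eta2(self) -> float:
        return self.eta2_hom - self.eta2_het


def delta_eta2(
    params: NoiseModelParams,
    lam_grid=(0.1, 0.5, 2.0, 10.0),
    a_grid=(0.5, 1.0, 2.0, 5.0),
) -> list[DeltaEtaResult]:
    """Mean-matched noise difference over a (lambda, a) grid.

    For each grid point: solve for lambda_bar, compute the heterozygote
    and homozygote decompositions, and report
    delta_eta2 = eta_hom^2 - eta_het^2.
    """
    rate = rate_f(params)
    out = []
    for lam in lam_grid:
        for a in a_grid:
            p = params.with_(lam=float(lam), a=float(a))
            lam_bar = match_mean(rate, p.lam, p.a, p.b)
            het = noise_decomposition(p, mode="het")
            hom = noise_decomposition(p, mode="hom", lam=lam_bar)
            out.append(
                DeltaEtaResult(
                    lam=p.lam,
                    a=p.a,
                    lam_bar=lam_bar,
                    eta2_het=het.eta2_total,
                    eta2_hom=hom.eta2_total,
                )
            )
    return out
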