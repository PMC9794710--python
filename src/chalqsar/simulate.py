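"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is the exact inverse of its fitter at zero noise, so
round-trip tests pin the numerics.  Noise models: additive Gaussian on
descriptor/activity responses, multiplicative Gaussian (constant CV) on
enzyme velocities — a conventional error structure for rate assays.
All randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, SchemaError
from .kinetics import DoseResponsePoint, InhibitionMode, KineticObservation, velocity
from .mlr import DataTable
from .pampa import PampaWell, equilibrium_concentration

__all__ = [
    "QsarSimSpec",
    "KineticSimSpec",
    "gen_qsar",
    "gen_kinetics",
    "gen_dose_response",
    "gen_pampa",
]


@dataclass(frozen=True)
class QsarSimSpec:
    """Correlated-Gaussian descriptor table with a known linear response.

    ``beta`` includes the intercept first; defaults mirror a 15-compound,
    3-descriptor series with the published coefficient signs.
    """

    n: int = 15
    p: int = 3
    beta: tuple[float, ...] = (4.3121, -0.1286, 0.0325, -1.4362)
    sigma: float = 0.3
    means: Optional[tuple[float, ...]] = None
    sds: Optional[tuple[float, ...]] = None
    corr: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise DomainError("sigma must be non-negative")
        if len(self.beta) != self.p + 1:
            raise SchemaError(f"beta needs {self.p + 1} entries (intercept first)")


def gen_qsar(spec: QsarSimSpec) -> DataTable:
    """X ~ correlated Gaussian, y = [1 X]·beta + N(0, sigma²)."""
    rng = np.random.default_rng(spec.seed)
    means = np.array(spec.means if spec.means is not None else np.zeros(spec.p), float)
    sds = np.array(spec.sds if spec.sds is not None else np.ones(spec.p), float)
    corr = np.asarray(spec.corr if spec.corr is not None else np.eye(spec.p), float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise SchemaError("correlation matrix is not positive definite") from exc
    Z = rng.standard_normal((spec.n, spec.p))
    X = means + (Z @ chol.T) * sds
    beta = np.asarray(spec.beta, float)
    y = beta[0] + X @ beta[1:] + rng.normal(0.0, spec.sigma, spec.n)
    return DataTable(
        ids=tuple(f"S{i + 1}" for i in range(spec.n)),
        X=X,
        y=y,
        descriptor_names=tuple(f"x{j + 1}" for j in range(spec.p)),
    )


@dataclass(frozen=True)
class KineticSimSpec:
    """Michaelis–Menten inhibition design mirroring the bench layout:
    five substrate levels spanning the Km and inhibitor levels around Ki."""

    vmax: float = 100.0
    km: float = 0.29  # mM
    ki: float = 0.030  # µM
    mode: InhibitionMode = InhibitionMode.COMPETITIVE
    alpha: float = 1.0
    substrate_levels: tuple[float, ...] = (0.0375, 0.075, 0.15, 0.3, 0.6)  # mM
    inhibitor_levels: tuple[float, ...] = (0.0, 0.015, 0.030, 0.060)  # µM
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be non-negative")
        for levels in (self.substrate_levels, self.inhibitor_levels):
            if len(set(levels)) != len(levels):
                raise SchemaError("levels must be distinct")


def gen_kinetics(spec: KineticSimSpec) -> list[KineticObservation]:
    """Velocities v = model(S, I) · (1 + N(0, cv)), truncated at 0."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i_conc in spec.inhibitor_levels:
        for s_conc in spec.substrate_levels:
            v = float(velocity(spec.vmax, spec.km, s_conc, i_conc, spec.ki, spec.mode, spec.alpha))
            if spec.noise_cv > 0:
                v *= 1.0 + rng.normal(0.0, spec.noise_cv)
            out.append(KineticObservation(s_conc, i_conc, max(v, 0.0)))
    return out


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    conc_grid: Sequence[float] = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[DoseResponsePoint]:
    """4-parameter-logistic activity curve with additive Gaussian noise."""
    if ic50 <= 0:
        raise DomainError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for conc in conc_grid:
        act = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
        if noise_sd > 0:
            act += rng.normal(0.0, noise_sd)
        points.append(DoseResponsePoint(conc, max(act, 0.0)))
    return points


def gen_pampa(
    true_pe: float,
    c_donor_initial: float = 1.0,
    v_donor: float = 0.27,
    v_acceptor: float = 0.20,
    area: float = 0.3,
    time: float = 64800.0,
    n_replicates: int = 1,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[PampaWell]:
    """Wells whose end-point concentrations encode a chosen true Pe.

    Inverts the permeability equation: mass conservation fixes
    C_eq = C_D0·V_D/(V_D+V_A), then
    C_A = C_eq·(1 − exp(−Pe·A·(1/V_D+1/V_A)·t)) and the donor concentration
    follows from the mass balance.  At zero noise
    :func:`chalqsar.pampa.effective_permeability` recovers ``true_pe``
    exactly.
    """
    if true_pe < 0:
        raise DomainError("true_pe must be non-negative")
    rng = np.random.default_rng(seed)
    c_eq = c_donor_initial * v_donor / (v_donor + v_acceptor)
    rate = true_pe * area * (1.0 / v_donor + 1.0 / v_acceptor) * time
    wells = []
    for _ in range(n_replicates):
        c_a = c_eq * (1.0 - np.exp(-rate))
        if noise_cv > 0:
            c_a *= 1.0 + rng.normal(0.0, noise_cv)
        c_a = float(np.clip(c_a, 0.0, None))
        c_d = (c_donor_initial * v_donor - c_a * v_acceptor) / v_donor
        if c_d < 0:
            raise SchemaError("parameters imply negative donor concentration")
        well = PampaWell(c_d, c_a, v_donor, v_acceptor, area, time)
        if c_a >= equilibrium_concentration(well) and true_pe > 0:
            raise SchemaError("parameters imply acceptor at equilibrium; shorten t or lower Pe")
        wells.append(well)
    return wells
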