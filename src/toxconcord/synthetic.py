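"""Synthetic toxicogenomics data with known ground truth.

Emulates the study design the analysis modules were built for: an
oligonucleotide-array-scale expression matrix (~20,000 probes) for one cell
line, with a vehicle/untreated control condition and several compound
treatments at 4 replicates each.  A configurable core of probes is perturbed
by *all* compounds with correlated log2 effect sizes (the "shared"
signature), each compound additionally perturbs a private probe set, and the
remainder is null.  Ground truth (memberships and exact effects) is emitted
alongside the matrix so downstream stages can be tested by parameter
recovery.

A second generator produces monotone-decreasing concentration-response
curves (percent of vehicle control versus micromolar concentration) with a
logistic mean structure, used to exercise IC50 estimation.

Effect-size model for shared probes
-----------------------------------
Each shared probe draws one fair-coin sign applied to all compounds, and a
magnitude vector ``effect_mean + effect_sd * g`` where ``g`` is jointly
Gaussian across compounds with an exchangeable latent correlation.  The
latent correlation is solved so that the realized Pearson correlation of two
compounds' signed effect vectors equals ``effect_correlation`` exactly:

    rho_latent = (rho * (mu^2 + sd^2) - mu^2) / sd^2

This is only feasible when ``effect_correlation`` is at least
``mu^2 / (mu^2 + sd^2)`` (the correlation already induced by the common
sign); configurations below that floor are rejected with an explanatory
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

DEFAULT_CONDITIONS = ("control", "BPA", "BPF", "BPS")
DEFAULT_CONCENTRATIONS = (0.0, 10.0, 50.0, 100.0, 250.0, 500.0)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the expression-matrix generator.

    Attributes
    ----------
    n_probes
        Universe size N (rows of the matrix).
    n_replicates
        Replicates per condition (columns per condition).
    conditions
        Condition labels; the first is the control.
    shared_de_count
        Probes perturbed by every compound.
    private_de_count
        Additional probes perturbed by exactly one compound, per compound.
    effect_mean, effect_sd
        Mean and SD of the log2 effect magnitude.
    effect_correlation
        Target Pearson correlation between compounds' signed effect vectors
        on shared probes, in [0, 1].
    noise_sd
        SD of i.i.d. Gaussian measurement noise on the log2 scale.
    baseline_mean, baseline_sd
        Per-probe baseline log2 intensity distribution.
    cell_line
        Label written to the sample sheet (one matrix = one cell line).
    seed
        Seed for the generator; identical (config, seed) pairs give
        bit-identical output.
    """

    n_probes: int = 20_000
    n_replicates: int = 4
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    shared_de_count: int = 150
    private_de_count: int = 100
    effect_mean: float = 1.0
    effect_sd: float = 1.5
    effect_correlation: float = 0.5
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    cell_line: str = "Man12"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ConfigurationError("n_probes must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if len(self.conditions) < 2:
            raise ConfigurationError(
                "conditions must contain a control plus at least one compound"
            )
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("conditions contains duplicate labels")
        if self.shared_de_count < 0:
            raise ConfigurationError("shared_de_count must be non-negative")
        if self.private_de_count < 0:
            raise ConfigurationError("private_de_count must be non-negative")
        needed = self.shared_de_count + len(self.compounds) * self.private_de_count
        if needed > self.n_probes:
            raise ConfigurationError(
                f"shared_de_count + compounds * private_de_count = {needed} "
                f"exceeds n_probes = {self.n_probes}"
            )
        if self.effect_sd < 0:
            raise ConfigurationError("effect_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.baseline_sd < 0:
            raise ConfigurationError("baseline_sd must be >= 0")
        if not 0.0 <= self.effect_correlation <= 1.0:
            raise ConfigurationError("effect_correlation must be in [0, 1]")
        # feasibility of the latent correlation (see module docstring)
        if self.shared_de_count > 0 and len(self.compounds) > 1:
            self._latent_correlation()

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def compounds(self) -> tuple[str, ...]:
        return self.conditions[1:]

    def _latent_correlation(self) -> float:
        mu2 = self.effect_mean**2
        sd2 = self.effect_sd**2
        rho = self.effect_correlation
        if sd2 == 0.0:
            if rho != 1.0:
                raise ConfigurationError(
                    "effect_correlation must be 1.0 when effect_sd is 0: "
                    "constant magnitudes with a common sign are perfectly "
                    "correlated"
                )
            return 1.0
        latent = (rho * (mu2 + sd2) - mu2) / sd2
        k = len(self.compounds)
        lower = -1.0 / (k - 1) if k > 1 else -1.0
        if latent < lower - 1e-12 or latent > 1.0 + 1e-12:
            floor = mu2 / (mu2 + sd2)
            raise ConfigurationError(
                f"effect_correlation={rho} is unreachable with "
                f"effect_mean={self.effect_mean}, effect_sd={self.effect_sd}: "
                f"the common sign alone induces correlation {floor:.3f}; "
                "increase effect_sd or raise effect_correlation"
            )
        return float(np.clip(latent, lower, 1.0))


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every synthetic matrix.

    ``effects`` holds the true per-probe log2 effect for every compound
    (0 for unaffected probes); ``membership`` labels each probe as
    ``shared``, ``private:<compound>`` or ``null``.
    """

    effects: pd.DataFrame
    membership: pd.Series

    @property
    def shared_probes(self) -> pd.Index:
        return self.membership.index[self.membership == "shared"]

    def perturbed_probes(self, compound: str) -> pd.Index:
        """Probes with a nonzero true effect under the given compound."""
        return self.effects.index[self.effects[compound] != 0.0]

    def to_json(self, path) -> None:
        payload = {
            "membership": self.membership.to_dict(),
            "effects": {c: self.effects[c].to_dict() for c in self.effects.columns},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        effects = pd.DataFrame(payload["effects"])
        effects.index.name = "probe_id"
        membership = pd.Series(payload["membership"], name="membership").loc[
            effects.index
        ]
        return cls(effects=effects, membership=membership)


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a log2 expression matrix plus its ground truth.

    Treated samples are ``baseline + true effect + noise``; control samples
    are ``baseline + noise``; noise is i.i.d. Gaussian on the log2 scale.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    compounds = list(config.compounds)
    k = len(compounds)
    probe_ids = pd.Index([f"P{i:06d}" for i in range(n)], name="probe_id")

    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)

    effects = pd.DataFrame(0.0, index=probe_ids, columns=compounds)
    membership = pd.Series("null", index=probe_ids, name="membership")

    # shared core: common sign, correlated Gaussian magnitudes
    n_shared = config.shared_de_count
    if n_shared > 0:
        shared_idx = probe_ids[:n_shared]
        membership.loc[shared_idx] = "shared"
        signs = rng.choice([-1.0, 1.0], size=n_shared)
        if config.effect_sd > 0 and k > 1:
            latent = config._latent_correlation()
            if latent >= 1.0 - 1e-12:  # singular limit: one draw per probe
                g = np.tile(rng.standard_normal((n_shared, 1)), (1, k))
            else:
                cov = np.full((k, k), latent)
                np.fill_diagonal(cov, 1.0)
                g = rng.multivariate_normal(
                    np.zeros(k), cov, size=n_shared, method="eigh"
                )
        else:
            g = rng.standard_normal((n_shared, k)) if config.effect_sd > 0 else np.zeros((n_shared, k))
        magnitudes = config.effect_mean + config.effect_sd * g
        effects.loc[shared_idx, :] = signs[:, None] * magnitudes

    # private sets: disjoint blocks after the shared core
    offset = n_shared
    for compound in compounds:
        m = config.private_de_count
        if m == 0:
            continue
        idx = probe_ids[offset : offset + m]
        membership.loc[idx] = f"private:{compound}"
        signs = rng.choice([-1.0, 1.0], size=m)
        mags = config.effect_mean + config.effect_sd * rng.standard_normal(m)
        effects.loc[idx, compound] = signs * mags
        offset += m

    r = config.n_replicates
    columns, data, rows = [], [], []
    for cond in config.conditions:
        eff = (
            effects[cond].to_numpy()
            if cond in effects.columns
            else np.zeros(n)
        )
        for rep in range(1, r + 1):
            noise = config.noise_sd * rng.standard_normal(n)
            data.append(baseline + eff + noise)
            columns.append(f"{cond}_r{rep}")
            rows.append((config.cell_line, cond, rep))

    values = pd.DataFrame(
        np.column_stack(data), index=probe_ids, columns=columns
    )
    samples = pd.DataFrame(
        rows,
        index=pd.Index(columns, name="sample_id"),
        columns=["cell_line", "treatment", "replicate"],
    )
    return ExpressionMatrix(values, samples), SyntheticTruth(effects, membership)


@dataclass(frozen=True)
class DoseResponseConfig:
    """Parameters of the concentration-response generator.

    ``concentrations`` are micromolar, strictly increasing, starting at 0
    (the vehicle).  When ``true_ic50`` is given, the mean curve is a
    logistic decay passing through 50 % of control exactly at that
    concentration; when absent, the mean response stays above 50 % across
    the tested range.
    """

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    true_ic50: float | None = 50.0
    hill_slope: float = 1.0
    response_floor: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 2:
            raise ConfigurationError("need at least two concentrations")
        if conc[0] != 0.0:
            raise ConfigurationError("first concentration must be 0 (vehicle)")
        if np.any(np.diff(conc) <= 0):
            raise ConfigurationError("concentrations must be strictly increasing")
        if self.hill_slope <= 0:
            raise ConfigurationError("hill_slope must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.true_ic50 is not None:
            if self.true_ic50 <= 0:
                raise ConfigurationError("true_ic50 must be positive")
            if self.response_floor >= 50.0:
                raise ConfigurationError(
                    "response_floor must be below 50 % for the curve to cross "
                    "the half-maximal response"
                )


def logistic_response(
    concentrations: np.ndarray, config: DoseResponseConfig
) -> np.ndarray:
    """Noise-free mean response (% of vehicle control) at each concentration.

    With an IC50 the curve is ``floor + (100 - floor) / (1 + (x/x0)^h)``
    with the midpoint ``x0`` solved so the response at ``true_ic50`` is
    exactly 50.  Without one, a shallow decay toward a floor above 50 is
    used, so the curve never reaches the half-maximal response.
    """
    x = np.asarray(concentrations, dtype=float)
    if config.true_ic50 is not None:
        floor = config.response_floor
        h = config.hill_slope
        # solve floor + (100-floor)/(1+(ic50/x0)^h) = 50 for x0
        x0 = config.true_ic50 * (50.0 / (50.0 - floor)) ** (-1.0 / h)
        resp = floor + (100.0 - floor) / (1.0 + (x / x0) ** h)
    else:
        floor = max(config.response_floor, 60.0)
        x0 = max(x) if len(x) else 1.0
        resp = floor + (100.0 - floor) / (1.0 + (x / x0) ** config.hill_slope)
    return resp


def generate_dose_response(config: DoseResponseConfig) -> pd.DataFrame:
    """Simulate one concentration-response curve.

    Returns a DataFrame with columns ``concentration_uM`` and
    ``response_pct``.  The vehicle point is fixed at 100 %; Gaussian noise
    (in percent units) is added to the treated points only.
    """
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations, dtype=float)
    resp = logistic_response(conc, config)
    resp[0] = 100.0
    if config.noise_sd > 0:
        resp[1:] = resp[1:] + config.noise_sd * rng.standard_normal(len(conc) - 1)
    return pd.DataFrame({"concentration_uM": conc, "response_pct": resp})
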