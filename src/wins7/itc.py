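"""Single-binding-site ITC forward model, fitter and thermodynamic decomposition.

The forward model is the standard 1:1 (Wiseman) isotherm: with total cell
concentrations M_t (macromolecule) and L_t (injectant) after the perfusion
dilution correction, the bound concentration is the physical root of the
binding quadratic,

    [ML] = ((N·M_t + L_t + K_D) − sqrt((N·M_t + L_t + K_D)² − 4·N·M_t·L_t)) / 2,

the cumulative heat is Q_i = ΔH·V0·[ML]_i, and the per-injection heat carries
the usual displaced-volume correction

    q_i = Q_i − Q_{i−1} + (v_i/V0)·(Q_i + Q_{i−1})/2 .

Fitting follows the statsmodels idiom: build :class:`SingleSiteModel` from a
thermogram and its titration setup, call :meth:`~SingleSiteModel.fit`, and
read estimates, standard errors and derived ΔG / −TΔS off the returned
:class:`ITCFit`. The fit is parameterised in log10(K_A) internally for
conditioning; ΔG = R·T·ln(K_D) at standard state 1 M with
R = 1.9872e-3 kcal/(mol·K), and −TΔS = ΔG − ΔH by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

R_KCAL = 1.9872e-3  # kcal/(mol*K)
DEFAULT_TEMPERATURE = 293.15  # K (20 degC)


class ITCError(Exception):
    pass


def default_injection_volumes() -> list[float]:
    """Instrument-style schedule: one 1 μL priming shot then 19 × 2 μL (litres)."""
    return [1e-6] + [2e-6] * 19


@dataclass
class TitrationSetup:
    """Cell/syringe concentrations (mol/L), volumes (L) and temperature (K)."""

    cell_volume: float = 200e-6
    cell_conc: float = 0.05e-3
    syringe_conc: float = 1.0e-3
    injection_volumes: list[float] = field(default_factory=default_injection_volumes)
    temperature: float = DEFAULT_TEMPERATURE
    discard_first: bool = True

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_conc, self.syringe_conc, self.temperature) <= 0:
            raise ITCError("setup quantities must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ITCError("injection volumes must be positive")

    def total_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """(M_t, L_t) in the cell after each injection, with the standard
        displacement factors for an overfilled perfusion cell."""
        v = np.asarray(self.injection_volumes, dtype=float)
        dv = np.cumsum(v)
        f = dv / (2.0 * self.cell_volume)
        mt = self.cell_conc * (1.0 - f) / (1.0 + f)
        lt = self.syringe_conc * (dv / self.cell_volume) / (1.0 + f)
        return mt, lt


@dataclass
class Thermogram:
    """Per-injection heats (μcal) plus the running total concentrations."""

    heats_ucal: np.ndarray
    mt: np.ndarray | None = None
    lt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        for name in ("mt", "lt"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if len(val) != len(self.heats_ucal):
                    raise ITCError(f"{name} length does not match heats")
                setattr(self, name, val)

    @property
    def molar_ratio(self) -> np.ndarray:
        if self.mt is None or self.lt is None:
            raise ITCError("thermogram carries no concentration ladder")
        return self.lt / self.mt

    def normalized_kcal_per_mol(self, setup: TitrationSetup) -> np.ndarray:
        """Heat per mole of injectant (kcal/mol), the conventional y-axis."""
        v = np.asarray(setup.injection_volumes, dtype=float)
        moles = setup.syringe_conc * v
        return (self.heats_ucal * 1e-9) / moles

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"injection": np.arange(1, len(self.heats_ucal) + 1),
             "heat_ucal": self.heats_ucal}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, setup: TitrationSetup | None = None) -> "Thermogram":
        df = pd.read_csv(path, sep="\t")
        if "heat_ucal" not in df.columns:
            raise ITCError(f"no heat_ucal column in {path}")
        heats = df["heat_ucal"].to_numpy(dtype=float)
        if setup is not None:
            if len(setup.injection_volumes) != len(heats):
                raise ITCError("setup injection count does not match thermogram")
            mt, lt = setup.total_concentrations()
            return cls(heats, mt, lt)
        return cls(heats)


def bound_concentration(mt, lt, n: float, k_d: float):
    """[ML] from the single-site binding quadratic (mol/L).

    Always the physical root: 0 ≤ [ML] ≤ min(N·M_t, L_t). A numerically
    negative discriminant is clamped to zero.
    """
    mt = np.asarray(mt, dtype=float)
    lt = np.asarray(lt, dtype=float)
    b = n * mt + lt + k_d
    disc = b * b - 4.0 * n * mt * lt
    disc = np.where(disc < 0, 0.0, disc)
    ml = 0.5 * (b - np.sqrt(disc))
    ml = np.minimum(ml, np.minimum(n * mt, lt))
    out = np.maximum(ml, 0.0)
    return float(out) if out.ndim == 0 else out


def _model_heats_ucal(setup: TitrationSetup, n: float, k_d: float, dh: float) -> np.ndarray:
    mt, lt = setup.total_concentrations()
    ml = bound_concentration(mt, lt, n, k_d)
    q = dh * setup.cell_volume * ml  # kcal
    v = np.asarray(setup.injection_volumes, dtype=float)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (v / setup.cell_volume) * (q + q_prev) / 2.0
    return dq * 1e9  # kcal -> ucal


def simulate_thermogram(
    setup: TitrationSetup,
    n: float,
    k_d: float,
    dh: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Thermogram:
    """Forward-model a titration; ``noise_sd`` is Gaussian heat noise in μcal,
    reproducible under ``seed``."""
    heats = _model_heats_ucal(setup, n, k_d, dh)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    mt, lt = setup.total_concentrations()
    return Thermogram(heats, mt, lt)


@dataclass
class ITCFit:
    """Fitted single-site parameters with derived state functions.

    ΔG = R·T·ln(K_D) and −TΔS = ΔG − ΔH hold exactly by construction.
    """

    n: float
    k_d: float
    dh: float
    temperature: float
    stderr: dict[str, float | None] = field(default_factory=dict)
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    c_value: float = float("nan")
    residual_rms_ucal: float = float("nan")

    @property
    def dg(self) -> float:
        return R_KCAL * self.temperature * np.log(self.k_d)

    @property
    def minus_tds(self) -> float:
        return self.dg - self.dh

    def to_dict(self) -> dict:
        return {
            "N": self.n,
            "K_D_M": self.k_d,
            "dH_kcal_mol": self.dh,
            "dG_kcal_mol": self.dg,
            "minus_TdS_kcal_mol": self.minus_tds,
            "temperature_K": self.temperature,
            "stderr": self.stderr,
            "converged": self.converged,
            "flags": self.flags,
            "c_value": self.c_value,
        }

    def summary(self) -> str:
        lines = [
            "Single-site ITC fit",
            "-" * 46,
            f"{'N (sites)':<22}{self.n:>12.3f}",
            f"{'K_D (uM)':<22}{self.k_d * 1e6:>12.3f}",
            f"{'dH (kcal/mol)':<22}{self.dh:>12.2f}",
            f"{'dG (kcal/mol)':<22}{self.dg:>12.2f}",
            f"{'-TdS (kcal/mol)':<22}{self.minus_tds:>12.2f}",
            f"{'c value':<22}{self.c_value:>12.1f}",
            f"{'converged':<22}{str(self.converged):>12}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


class SingleSiteModel:
    """1:1 binding model bound to one thermogram and its titration setup."""

    def __init__(self, thermogram: Thermogram, setup: TitrationSetup):
        if len(thermogram.heats_ucal) != len(setup.injection_volumes):
            raise ITCError("thermogram and setup disagree on injection count")
        usable = len(thermogram.heats_ucal) - (1 if setup.discard_first else 0)
        if usable < 6:
            raise ITCError(f"need at least 6 usable injections, have {usable}")
        self.thermogram = thermogram
        self.setup = setup

    # -- initialisation -----------------------------------------------------
    def _initial_guess(self, policy: str = "midpoint") -> tuple[float, float, float]:
        """(N0, K_D0, ΔH0) from the integrated-heat midpoint.

        ΔH0 comes from the earliest retained normalized heat, N0 from the
        molar ratio at which the cumulative heat reaches half its total, and
        K_D0 from assuming a mid-range sigmoidicity (c ≈ 20).
        """
        if policy != "midpoint":
            raise ITCError(f"unknown init policy: {policy!r}")
        start = 1 if self.setup.discard_first else 0
        ndh = self.thermogram.normalized_kcal_per_mol(self.setup)[start:]
        ratio = self.thermogram.molar_ratio[start:]
        dh0 = float(ndh[0])
        if dh0 == 0:
            dh0 = float(ndh[np.argmax(np.abs(ndh))]) or -1.0
        cum = np.cumsum(ndh)
        half = cum[-1] / 2.0
        idx = int(np.argmin(np.abs(cum - half)))
        n0 = float(np.clip(ratio[idx], 0.3, 3.0))
        k_d0 = n0 * self.setup.cell_conc / 20.0
        return n0, k_d0, dh0

    # -- fitting ------------------------------------------------------------
    def fit(self, init_policy: str = "midpoint") -> ITCFit:
        """Least-squares fit of (N, K_D, ΔH); the first injection is dropped
        when the setup flags it. Degenerate (flat) data are flagged
        unreliable, never silently returned as converged."""
        start = 1 if self.setup.discard_first else 0
        obs = self.thermogram.heats_ucal
        mask = np.zeros(len(obs), dtype=bool)
        mask[start:] = True

        span = float(np.ptp(obs[mask]))
        if span < 1e-9 or not np.all(np.isfinite(obs)):
            return ITCFit(
                n=float("nan"), k_d=float("nan"), dh=float("nan"),
                temperature=self.setup.temperature,
                converged=False, flags=["unreliable: flat or non-finite thermogram"],
            )

        n0, k_d0, dh0 = self._initial_guess(init_policy)
        params = lmfit.Parameters()
        params.add("n", value=n0, min=0.05, max=10.0)
        params.add("log10_ka", value=-np.log10(k_d0), min=0.0, max=12.0)
        params.add("dh", value=dh0)

        def residual(p):
            model = _model_heats_ucal(
                self.setup, p["n"].value, 10.0 ** (-p["log10_ka"].value), p["dh"].value
            )
            return model[mask] - obs[mask]

        result = lmfit.minimize(residual, params, method="leastsq")
        n = float(result.params["n"].value)
        k_d = float(10.0 ** (-result.params["log10_ka"].value))
        dh = float(result.params["dh"].value)
        c_value = n * self.setup.cell_conc / k_d

        stderr: dict[str, float | None] = {"n": None, "k_d": None, "dh": None}
        if result.params["n"].stderr is not None:
            stderr["n"] = float(result.params["n"].stderr)
        if result.params["dh"].stderr is not None:
            stderr["dh"] = float(result.params["dh"].stderr)
        if result.params["log10_ka"].stderr is not None:
            # delta method: K_D = 10^(-x) => sd(K_D) = ln(10) * K_D * sd(x)
            stderr["k_d"] = float(np.log(10.0) * k_d * result.params["log10_ka"].stderr)

        flags = []
        if c_value < 1.0:
            flags.append(f"unreliable: c value {c_value:.2f} below 1")
        fit = ITCFit(
            n=n, k_d=k_d, dh=dh,
            temperature=self.setup.temperature,
            stderr=stderr,
            converged=bool(result.success) and not flags,
            flags=flags,
            c_value=float(c_value),
            residual_rms_ucal=float(np.sqrt(np.mean(result.residual ** 2))),
        )
        return fit


def fit_single_site(
    thermogram: Thermogram, setup: TitrationSetup, init_policy: str = "midpoint"
) -> ITCFit:
    """Functional wrapper over :class:`SingleSiteModel`."""
    return SingleSiteModel(thermogram, setup).fit(init_policy=init_policy)


def decompose(k_d: float, dh: float, temperature: float = DEFAULT_TEMPERATURE):
    """(ΔG, −TΔS) in kcal/mol from K_D (mol/L) and ΔH (kcal/mol)."""
    if k_d <= 0:
        raise ITCError("K_D must be positive")
    dg = R_KCAL * temperature * np.log(k_d)
    return dg, dg - dh


def fold_change(k_d_variant: float, k_d_reference: float) -> float:
    """Affinity loss of a variant as K_D(variant) / K_D(reference)."""
    return k_d_variant / k_d_reference
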