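"""Synthetic replicated NIR-like reflectance datasets with known error structure.

Because miniaturized-sensor replicate studies rarely deposit raw spectra, this
module generates datasets that emulate the replicate/session/background design
of such a study and carry a *known* theoretical error covariance, so every
estimator in the package can be validated against a closed form.

The generative model for replicate i at channel j is

    x_ij = μ_j (1 + m_i) + o_i + s_sess(i) + b_mode(i)
           + σ_shot √μ_j η_ij + ε_ij

with per-replicate gain error m_i ~ N(0, σ_mult²), per-replicate offset
o_i ~ N(0, σ_offset²), a per-session shift s ~ N(0, σ_session²), an extra
offset b ~ N(0, δ_background²) drawn once per mode-B session (background taken
only at session start, so drift accumulates), and channel-wise shot
(variance ∝ μ_j) and independent noise. All draws are Gaussian.

The implied error covariance seen by a replicate grouping is

    Σ = σ_offset²·J + σ_mult²·μμᵀ + σ_shot²·diag(μ) + σ_iid²·I  [+ session terms]

where J is the all-ones matrix; groupings that pool across sessions
additionally see σ_session²·J (and the mode-B δ_background²·J share).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, SpectraDataset, WavelengthAxis
from .error_structure import ErrorCovariance

__all__ = [
    "InstrumentProfile",
    "NoiseModel",
    "DesignSpec",
    "SampleEffect",
    "AVASPEC_LIKE",
    "NEOSPECTRA_LIKE",
    "DEFAULT_SAMPLE_EFFECTS",
    "base_spectrum",
    "simulate_dataset",
    "theoretical_ecm",
]


@dataclass(frozen=True)
class InstrumentProfile:
    """Wavelength range, channel count and base-spectrum shape of a sensor."""

    name: str
    wl_min: float
    wl_max: float
    channels: int
    bands: tuple[tuple[float, float, float], ...]  # (center nm, width nm, amplitude %R)
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if not self.wl_min < self.wl_max:
            raise ValueError("wl_min must be below wl_max")
        if self.channels < 2:
            raise ValueError("need at least 2 channels")
        if any(a < 0 for _, _, a in self.bands):
            raise ValueError("band amplitudes must be non-negative")


# Built-in profiles emulating the two sensor geometries: a dispersive
# fiber-probe unit (many channels, shorter NIR, higher reflectance) and a
# direct-contact FT unit (few channels, longer NIR, lower reflectance). Band
# positions are loosely placed at sucrose OH/CH overtone and combination
# regions; they stand in for real mean spectra, not reproduce them.
AVASPEC_LIKE = InstrumentProfile(
    name="avaspec_like",
    wl_min=972.0,
    wl_max=1701.0,
    channels=236,
    bands=((1100.0, 90.0, 12.0), (1250.0, 60.0, 8.0), (1440.0, 70.0, 22.0),
           (1590.0, 80.0, 10.0)),
    baseline=14.0,
)

NEOSPECTRA_LIKE = InstrumentProfile(
    name="neospectra_like",
    wl_min=1351.0,
    wl_max=2559.0,
    channels=74,
    bands=((1440.0, 70.0, 8.0), (1790.0, 90.0, 10.0), (2100.0, 110.0, 14.0),
           (2330.0, 80.0, 6.0)),
    baseline=6.0,
)

PROFILES = {p.name: p for p in (AVASPEC_LIKE, NEOSPECTRA_LIKE)}


@dataclass(frozen=True)
class NoiseModel:
    """Variance components of the measurement-error model (all σ in %R except
    σ_mult, dimensionless, and σ_shot, in %R^½ units)."""

    sigma_offset: float = 1.0
    sigma_mult: float = 0.04
    sigma_shot: float = 0.12
    sigma_iid: float = 0.05
    sigma_session: float = 0.8
    delta_background: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_offset", "sigma_mult", "sigma_shot", "sigma_iid",
                     "sigma_session", "delta_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SampleEffect:
    """Deterministic per-sample signal modification (gain and level shift)."""

    gain: float = 1.0
    shift: float = 0.0


#: Two sugar presentations: lumps give the nominal signal, granulated sugar a
#: slightly attenuated one (different packing and light path).
DEFAULT_SAMPLE_EFFECTS = {
    "sugar_lump": SampleEffect(gain=1.0, shift=0.0),
    "granulated_sugar": SampleEffect(gain=0.88, shift=-1.5),
}


@dataclass(frozen=True)
class DesignSpec:
    """Replicate/session/background layout of a study.

    Defaults emulate the reference design: 3 sessions under background mode A
    (background before each sample) and 3 under mode B (background at session
    start), 15 replicates each — 90 replicates per sample.
    """

    samples: tuple[str, ...] = ("sugar_lump", "granulated_sugar")
    sessions_per_mode: int = 3
    replicates_per_session: int = 15
    instrument: InstrumentProfile = AVASPEC_LIKE

    @property
    def n_sessions(self) -> int:
        return 2 * self.sessions_per_mode

    @property
    def n_rows(self) -> int:
        return len(self.samples) * self.n_sessions * self.replicates_per_session

    @property
    def session_ids(self) -> list[tuple[str, str]]:
        """(session label, background mode) pairs, e.g. ('1A', 'A') … ('3B', 'B')."""
        out = []
        for mode in ("A", "B"):
            for s in range(1, self.sessions_per_mode + 1):
                out.append((f"{s}{mode}", mode))
        return out


def base_spectrum(profile: InstrumentProfile) -> np.ndarray:
    """Noise-free mean spectrum μ on the profile's wavelength grid.

    μ_j = baseline + Σ_bands amplitude · exp(−(λ_j − center)² / (2 width²));
    strictly positive by construction.
    """
    wl = np.linspace(profile.wl_min, profile.wl_max, profile.channels)
    mu = np.full(profile.channels, float(profile.baseline))
    for center, width, amplitude in profile.bands:
        mu += amplitude * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return mu


def wavelength_axis(profile: InstrumentProfile) -> WavelengthAxis:
    return WavelengthAxis(np.linspace(profile.wl_min, profile.wl_max, profile.channels))


def simulate_dataset(
    design: DesignSpec = DesignSpec(),
    noise: NoiseModel = NoiseModel(),
    sample_effects: dict[str, SampleEffect] | None = None,
    seed: int | None = None,
) -> SpectraDataset:
    """Draw a replicated dataset from the generative error model.

    ``seed`` overrides ``noise.seed``; for a fixed seed the output is
    bit-reproducible. Session and background effects are drawn once per
    session; the mode-B background offset applies only to mode-B sessions.
    """
    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(seed)
    profile = design.instrument
    mu = base_spectrum(profile)
    wl = np.linspace(profile.wl_min, profile.wl_max, profile.channels)
    if sample_effects is None:
        sample_effects = {
            s: DEFAULT_SAMPLE_EFFECTS.get(s, SampleEffect()) for s in design.samples
        }
    rows, meta_rows = [], []
    for sample in design.samples:
        eff = sample_effects.get(sample, SampleEffect())
        mu_s = np.clip(mu * eff.gain + eff.shift, 1e-6, None)
        for session_id, mode in design.session_ids:
            s_shift = rng.normal(0.0, noise.sigma_session)
            b_shift = (
                rng.normal(0.0, noise.delta_background) if mode == "B" else 0.0
            )
            for rep in range(1, design.replicates_per_session + 1):
                m = rng.normal(0.0, noise.sigma_mult)
                o = rng.normal(0.0, noise.sigma_offset)
                shot = noise.sigma_shot * np.sqrt(mu_s) * rng.standard_normal(mu_s.size)
                eps = noise.sigma_iid * rng.standard_normal(mu_s.size)
                rows.append(mu_s * (1.0 + m) + o + s_shift + b_shift + shot + eps)
                meta_rows.append(
                    (sample, session_id, mode, rep, profile.name)
                )
    X = np.vstack(rows)
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    return SpectraDataset(X, WavelengthAxis(wl), meta)


def theoretical_ecm(
    noise: NoiseModel,
    mu: np.ndarray,
    grouping: str = "per_session",
    background_mode: str | None = None,
    mode_b_fraction: float = 0.5,
) -> ErrorCovariance:
    """Closed-form error covariance implied by the generative model.

    Per-session grouping removes the session and background shifts (they are
    constant within a group, hence absorbed by the group mean):

        Σ = σ_offset²·J + σ_mult²·μμᵀ + σ_shot²·diag(μ) + σ_iid²·I.

    Per-background-mode grouping additionally sees σ_session²·J (plus
    δ_background²·J when ``background_mode='B'``); pooling over everything
    (``grouping='all'``) sees σ_session²·J plus the mode-B fraction of
    δ_background²·J.
    """
    mu = np.asarray(mu, dtype=float)
    p = mu.size
    J = np.ones((p, p))
    Sigma = (
        noise.sigma_offset**2 * J
        + noise.sigma_mult**2 * np.outer(mu, mu)
        + noise.sigma_shot**2 * np.diag(mu)
        + noise.sigma_iid**2 * np.eye(p)
    )
    if grouping == "per_session":
        pass
    elif grouping == "per_background_mode":
        extra = noise.sigma_session**2
        if background_mode == "B":
            extra += noise.delta_background**2
        Sigma = Sigma + extra * J
    elif grouping == "all":
        Sigma = Sigma + (
            noise.sigma_session**2 + mode_b_fraction * noise.delta_background**2
        ) * J
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return ErrorCovariance(Sigma, n_effective=0)
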