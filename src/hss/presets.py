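"""Strain presets and noise-model parameters for the HSS generative model.

A *strain preset* collects the per-generation kinetic parameters of the
spreading random walk (nucleation gain/loss, restoring drift toward the
repressed state, turnover-scaled noise) together with the phenomenological
curve parameters used by the dose-response and heat-recovery generators
(half-resistance concentration, memory offset, half-recovery time).

Presets ship as a versioned YAML document (``hss/data/presets.yaml``) whose
numeric values were calibrated once, by grid search, against the benchmark
population and trace fractions the pipeline is expected to reproduce
(see ``scripts/calibrate_presets.py``). Presets are immutable after loading.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "StrainParams",
    "NoiseModel",
    "BinPreset",
    "load_config",
    "default_config",
    "get_preset",
]

_PROB_FIELDS = ("k_nuc", "k_denuc", "k_loss")
_NONNEG_FIELDS = ("k_restore", "sigma_s", "distance_kb", "memory_offset")
_POS_FIELDS = ("half_resistance_uM", "recovery_t_half_hr", "doubling_time_hr")


@dataclass(frozen=True)
class StrainParams:
    """Generative parameters for one strain preset.

    Parameters
    ----------
    name:
        Preset label (e.g. ``WT_MAT``, ``dREIII``, ``ectopic_dh_3kb``).
    k_nuc, k_denuc:
        Per-generation probability of gaining / losing nucleation.
    k_restore:
        Per-generation restoring drift of the spreading de-repression level
        ``s`` toward 0 (full repression) while nucleated; dimensionless.
    sigma_s:
        Per-generation Gaussian noise scale of the spreading walk. This is
        the histone-turnover proxy: high in strains with near-euchromatic
        replication-independent H3 exchange, ~0 where turnover is repressed.
    k_loss:
        Per-generation relaxation of ``s`` toward 1 (de-repression) while not
        nucleated.
    distance_kb:
        Distance of the distal ("orange") reporter from the nucleator, kb.
        0 for MAT-locus presets.
    half_resistance_uM:
        TSA concentration at which the normalized orange-OFF fraction of
        untreated-ancestry cells declines to 50%.
    memory_offset:
        Normalized-scale OFF-fraction advantage of untreated over TSA
        pretreated ancestry at 0 µM.
    renucleates_after_erasure:
        False for ΔK-type presets, whose ncRNA nucleator is deleted and which
        cannot re-establish heterochromatin after full erasure.
    recovery_t_half_hr:
        Half-recovery time of full spreading after transient 38°C exposure.
    recovery_floor:
        Lower asymptote of the 32°C-normalized recovery curve (fraction of
        full spreading retained immediately after the perturbation).
    off_fraction_0uM:
        Absolute orange-OFF fraction among nucleated cells at 0 µM TSA,
        before normalization.
    doubling_time_hr:
        Generation time in hours (default 2.3 hr).
    """

    name: str
    k_nuc: float = 0.0
    k_denuc: float = 0.0
    k_restore: float = 0.0
    sigma_s: float = 0.0
    k_loss: float = 0.0
    distance_kb: float = 0.0
    half_resistance_uM: float = 1.0
    memory_offset: float = 0.0
    renucleates_after_erasure: bool = True
    recovery_t_half_hr: float = 1.0
    recovery_floor: float = 0.0
    off_fraction_0uM: float = 0.9
    doubling_time_hr: float = 2.3
    xfp_free: bool = False

    def __post_init__(self) -> None:
        for f in _PROB_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"preset {self.name!r}: {f}={v} outside [0, 1]")
        for f in _NONNEG_FIELDS:
            v = getattr(self, f)
            if v < 0:
                raise ValueError(f"preset {self.name!r}: {f}={v} must be >= 0")
        for f in _POS_FIELDS:
            v = getattr(self, f)
            if v <= 0:
                raise ValueError(f"preset {self.name!r}: {f}={v} must be > 0")
        if not 0.0 <= self.recovery_floor <= 1.0:
            raise ValueError(
                f"preset {self.name!r}: recovery_floor={self.recovery_floor} outside [0, 1]"
            )
        if not 0.0 <= self.off_fraction_0uM <= 1.0:
            raise ValueError(
                f"preset {self.name!r}: off_fraction_0uM={self.off_fraction_0uM} outside [0, 1]"
            )

    def replace(self, **kwargs) -> "StrainParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Fluorescence rendering model shared by all presets.

    ``extrinsic_sd`` is the log-scale SD of the lognormal cell factor F shared
    multiplicatively by all three channels (cell-to-cell variation in general
    expression capacity, reported by the euchromatic "red" channel).
    ``channel_sd`` is the per-channel independent lognormal SD. ``leak`` is
    the residual promoter activity of a fully repressed reporter, as a
    fraction of full expression. Background (autofluorescence) is lognormal
    with the given mean/sd in raw fluorescence units. ``trace_channel_sd``
    and ``trace_tau_hr`` govern the time-lapse rendering: a smaller
    per-sample noise (frame-to-frame measurement error) and a first-order
    relaxation time constant emulating fluorophore maturation/dilution.
    """

    amp_green: float = 1000.0
    amp_orange: float = 1000.0
    amp_red: float = 1000.0
    extrinsic_sd: float = 0.40
    channel_sd: float = 0.15
    leak: float = 0.01
    bg_mean: float = 20.0
    bg_sd: float = 6.0
    fsc_scale: float = 50000.0
    ssc_scale: float = 30000.0
    scatter_sd: float = 0.10
    trace_channel_sd: float = 0.035
    trace_tau_hr: float = 1.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"noise model: {f.name}={v} must be >= 0")
        if not 0 <= self.leak < 1:
            raise ValueError(f"noise model: leak={self.leak} outside [0, 1)")


@dataclass(frozen=True)
class BinPreset:
    """Ground truth for one FACS-sorted orange bin (low / intermediate / high).

    Values are on the normalized scales the enrichment module reports:
    expression as a fraction of the Δclr4 maximum, ChIP densities as a
    fraction of the assay's positive control (dh repeat for H3K9me2, act1
    promoter for H3K4me3).
    """

    name: str
    expression: float
    h3k9me2: float
    h3k4me3: float

    def __post_init__(self) -> None:
        for f in ("expression", "h3k9me2", "h3k4me3"):
            v = getattr(self, f)
            if not 0 <= v <= 1.5:
                raise ValueError(f"bin preset {self.name!r}: {f}={v} implausible")


@dataclass(frozen=True)
class Config:
    presets: Mapping[str, StrainParams]
    noise: NoiseModel
    bins: Mapping[str, BinPreset]
    rite: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def preset(self, name: str) -> StrainParams:
        try:
            return self.presets[name]
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(self.presets)}"
            ) from None


_ALLOWED_TOP = {"presets", "noise", "bins", "rite"}


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a preset configuration (YAML or JSON document).

    With ``path=None`` the packaged default configuration is loaded. Unknown
    keys are rejected; invariant violations raise ``ValueError`` naming the
    preset and field.
    """
    if path is None:
        text = resources.files("hss.data").joinpath("presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    unknown = set(doc) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    param_fields = {f.name for f in dataclasses.fields(StrainParams)} - {"name"}
    presets = {}
    for name, spec in (doc.get("presets") or {}).items():
        extra = set(spec) - param_fields
        if extra:
            raise ValueError(f"preset {name!r}: unknown fields {sorted(extra)}")
        presets[name] = StrainParams(name=name, **spec)

    noise_fields = {f.name for f in dataclasses.fields(NoiseModel)}
    noise_spec = doc.get("noise") or {}
    extra = set(noise_spec) - noise_fields
    if extra:
        raise ValueError(f"noise model: unknown fields {sorted(extra)}")
    noise = NoiseModel(**noise_spec)

    bins = {}
    for name, spec in (doc.get("bins") or {}).items():
        bins[name] = BinPreset(name=name, **spec)

    rite = {k: dict(v) for k, v in (doc.get("rite") or {}).items()}
    return Config(presets=presets, noise=noise, bins=bins, rite=rite)


_DEFAULT: Config | None = None


def default_config() -> Config:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_config(None)
    return _DEFAULT


def get_preset(name: str) -> StrainParams:
    """Shorthand for ``default_config().preset(name)``."""
    return default_config().preset(name)
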