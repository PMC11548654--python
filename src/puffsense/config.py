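"""YAML-backed pipeline configuration.

A single ``PipelineConfig`` collects the optics, emission, flow, optical
path, noise and training settings plus dataset sizes.  Every pipeline run
writes the resolved configuration next to its outputs so results are
self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .optics import DEFAULT_BIN_EDGES, OpticalWavelengthBand, ParticleOpticalProperties
from .simulate import EmissionModel, FlowModel, NoiseSpec, OpticalPathConfig

__all__ = ["PipelineConfig", "load_config", "validate_config"]


@dataclass(frozen=True)
class BandConfig:
    center_wavelength: float
    fwhm_bandwidth: float
    label: str

    def to_band(self) -> OpticalWavelengthBand:
        return OpticalWavelengthBand(self.center_wavelength, self.fwhm_bandwidth, self.label)


@dataclass(frozen=True)
class TrainingSection:
    layer_size: int = 8
    train_fraction: float = 0.85
    max_epochs: int = 300
    patience: int = 6
    activation: str = "tanh"


@dataclass(frozen=True)
class DatasetSection:
    n_train: int = 100
    n_test: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    bands: tuple = (
        BandConfig(370.0, 10.0, "UV"),
        BandConfig(640.0, 17.0, "R"),
        BandConfig(940.0, 50.0, "IR"),
    )
    refractive_index_real: float = 1.45
    refractive_index_imag: float = 0.0
    material_density: float = 1.12
    bin_edges: tuple = DEFAULT_BIN_EDGES
    emission: EmissionModel = field(default_factory=EmissionModel)
    flow: FlowModel = field(default_factory=FlowModel)
    path: OpticalPathConfig = field(default_factory=OpticalPathConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    training: TrainingSection = field(default_factory=TrainingSection)
    dataset: DatasetSection = field(default_factory=DatasetSection)

    def optics(self) -> ParticleOpticalProperties:
        return ParticleOpticalProperties(
            self.refractive_index_real, self.refractive_index_imag, self.material_density
        )

    def optical_bands(self):
        return tuple(b.to_band() for b in self.bands)

    def bins(self):
        e = self.bin_edges
        return [(e[0], e[1]), (e[1], e[2]), (e[2], e[3])]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_SECTION_TYPES = {
    "emission": EmissionModel,
    "flow": FlowModel,
    "path": OpticalPathConfig,
    "noise": NoiseSpec,
    "training": TrainingSection,
    "dataset": DatasetSection,
}


def _build_section(cls, data: dict, warnings_out: list, prefix: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        warnings_out.append(f"unknown key {prefix}{key!r} ignored")
    return cls(**{k: v for k, v in data.items() if k in known})


def load_config(path=None, warnings_out: list | None = None) -> PipelineConfig:
    """Load a YAML config (or defaults if path is None); unknown keys warn."""
    if warnings_out is None:
        warnings_out = []
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")

    kwargs = {}
    top_known = {f.name for f in fields(PipelineConfig)}
    for key in sorted(set(data) - top_known):
        warnings_out.append(f"unknown key {key!r} ignored")
    for key, value in data.items():
        if key not in top_known:
            continue
        if key == "bands":
            kwargs["bands"] = tuple(
                _build_section(BandConfig, b, warnings_out, "bands.") for b in value
            )
        elif key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, warnings_out, f"{key}.")
        elif key == "bin_edges":
            kwargs[key] = tuple(float(v) for v in value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def validate_config(config: PipelineConfig) -> list:
    """Return a list of error strings; empty means the config is valid."""
    errors = []
    try:
        bands = config.optical_bands()
        if len(bands) != 3:
            errors.append("exactly three wavelength bands are required")
    except ValueError as exc:
        errors.append(f"bands: {exc}")
    try:
        config.optics()
    except ValueError as exc:
        errors.append(f"optics: {exc}")
    edges = config.bin_edges
    if len(edges) != 4 or any(b <= a for a, b in zip(edges, edges[1:])):
        errors.append("bin_edges must be four strictly increasing diameters")
    if not (0 < config.training.train_fraction < 1):
        errors.append("training.train_fraction must be in (0, 1)")
    if config.training.layer_size < 1:
        errors.append("training.layer_size must be >= 1")
    if config.dataset.n_train < 10:
        errors.append("dataset.n_train must be >= 10")
    if config.dataset.n_test < 1:
        errors.append("dataset.n_test must be >= 1")
    for section in ("emission", "flow", "path", "noise"):
        obj = getattr(config, section)
        try:
            replace(obj)
        except ValueError as exc:  # pragma: no cover - dataclass revalidation
            errors.append(f"{section}: {exc}")
    return errors
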