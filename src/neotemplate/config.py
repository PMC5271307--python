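"""Pipeline configuration: one serializable object collecting every setting.

Round-trips losslessly through YAML (``PipelineConfig.from_yaml(p.to_yaml())
== p``), so a run is fully reproducible from its config file plus the input
images.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .levelset import LevelSetParams
from .registration import AffineParams, SynParams

__all__ = ["PipelineConfig"]


def _tupled(obj):
    """YAML loads tuples as lists; restore tuples recursively for dataclass eq."""
    if isinstance(obj, list):
        return tuple(_tupled(x) for x in obj)
    return obj


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the template-construction pipeline.

    Defaults follow the reference protocol: 0.47 mm isotropic re-slicing,
    the CT intensity transform enabled, 2 template iterations, MI for the
    inter-modality steps, CC for intra-modality evaluation normalization,
    2 mm FWHM template smoothing before MI evaluation, 64 evaluation bins,
    base-2 logarithms.
    """

    iso_spacing: float = 0.47
    intensity_transform: bool = True
    opening_radius: int = 1
    closing_radius: int = 2
    inner_erosion_mm: float = 15.0
    levelset: LevelSetParams = dataclasses.field(default_factory=LevelSetParams)
    affine: AffineParams = dataclasses.field(default_factory=AffineParams)
    syn: SynParams = dataclasses.field(default_factory=SynParams)
    template_iterations: int = 2
    registration_metric: str = "MI"   # CT->MR steps (inter-modality)
    evaluation_metric: str = "CC"     # test-image normalization
    evaluation_fwhm_mm: float = 2.0
    evaluation_bins: int = 64
    log_base: float = 2.0
    seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("levelset", LevelSetParams),
                         ("affine", AffineParams), ("syn", SynParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: _tupled(v) for k, v in d[key].items()})
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and "\n" not in source
                                        and Path(source).exists()):
            source = Path(source).read_text()
        return cls.from_dict(yaml.safe_load(source))
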