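"""End-to-end orchestration: enhancement through thickness measurement.

``run_pipeline`` executes the fixed stage order — cartilage enhancement,
bone-feature extraction, shadow modelling, DP bone localization, seed
generation, seeded segmentation, thickness measurement — and returns every
intermediate for inspection. The orchestration is purely functional:
identical (image, config) pairs produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .bonefeatures import BoneFeatureParams, PhaseFeatureSet, compute_phase_features
from .enhancement import EnhancedImage, enhance_cartilage
from .io import BModeImage, load_config_dict, save_config
from .localization import BoneSurface, LocalizationParams, localize_bone
from .quadfilters import EnhancementParams
from .segmentation import (
    GCParams,
    RWParams,
    SeedParams,
    SegmentationResult,
    segment,
)
from .shadow import ShadowParams, ShadowSet, compute_shadow_set
from .thickness import ThicknessResult, thickness_from_mask


class PipelineStageError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the pipeline, serializable to YAML."""

    enhancement: EnhancementParams = field(default_factory=EnhancementParams)
    bone: BoneFeatureParams = field(default_factory=BoneFeatureParams)
    shadow: ShadowParams = field(default_factory=ShadowParams)
    localization: LocalizationParams = field(default_factory=LocalizationParams)
    seeding: SeedParams = field(default_factory=SeedParams)
    rw: RWParams = field(default_factory=RWParams)
    gc: GCParams = field(default_factory=GCParams)
    backend: str = "rw"

    def save(self, path) -> None:
        save_config(path, self)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(load_config_dict(path))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, section):
            payload = dict(data.get(section, {}))
            # YAML round-trips tuples as lists
            for f in dataclasses.fields(klass):
                if f.name in payload and isinstance(payload[f.name], list):
                    payload[f.name] = tuple(payload[f.name])
            return klass(**payload)

        return cls(
            enhancement=build(EnhancementParams, "enhancement"),
            bone=build(BoneFeatureParams, "bone"),
            shadow=build(ShadowParams, "shadow"),
            localization=build(LocalizationParams, "localization"),
            seeding=build(SeedParams, "seeding"),
            rw=build(RWParams, "rw"),
            gc=build(GCParams, "gc"),
            backend=data.get("backend", "rw"),
        )


@dataclass(frozen=True)
class PipelineResult:
    enhanced: EnhancedImage
    features: PhaseFeatureSet
    shadow: ShadowSet
    surface: BoneSurface
    segmentation: SegmentationResult
    thickness: ThicknessResult | None  # None when no cartilage was found


def run_pipeline(
    image: BModeImage,
    config: PipelineConfig | None = None,
    use_enhanced_input: bool = True,
) -> PipelineResult:
    """Run every stage in order on one B-mode frame.

    ``use_enhanced_input=False`` feeds the raw B-mode pixels to the
    segmentation backend instead of the enhanced map (the ablation mode);
    enhancement still runs, since localization depends on it.
    """
    if config is None:
        config = PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    enhanced = stage("enhancement", enhance_cartilage, image, config.enhancement)
    features = stage("bone_features", compute_phase_features, enhanced, config.bone)
    shadow_set = stage("shadow", compute_shadow_set, features.lp, config.shadow)
    surface = stage(
        "localization",
        localize_bone,
        features.lp,
        shadow_set.bse,
        config.localization,
        spacing_mm=image.spacing_mm,
    )
    seed_params = dataclasses.replace(config.seeding, spacing_mm=image.spacing_mm)
    seg_input = enhanced if use_enhanced_input else image.pixels
    seg = stage(
        "segmentation",
        segment,
        seg_input,
        surface,
        backend=config.backend,
        seed_params=seed_params,
        rw_params=config.rw,
        gc_params=config.gc,
    )
    thick = None
    if seg.found:
        thick = stage("thickness", thickness_from_mask, seg.mask, image.spacing_mm)
    return PipelineResult(
        enhanced=enhanced,
        features=features,
        shadow=shadow_set,
        surface=surface,
        segmentation=seg,
        thickness=thick,
    )
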