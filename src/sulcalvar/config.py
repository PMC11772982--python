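"""Parameter containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a parameter container violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the analysed study design at desk scale: 30 case
    participants with both genome and imaging data, a 94-participant
    imaging reference cohort, and a planted effect on a small subset of
    annotations whose per-participant score maxima correlate with a
    sulcal trait at ``planted_trait_r``.
    """

    seed: int = 0
    n_case: int = 30
    n_control: int = 94
    n_annotations: int = 100
    variants_per_participant_mean: float = 20.0
    effect_annotation_count: int = 10
    #: score s.d. multiplier for the case cohort on effect annotations
    tail_inflation: float = 1.5
    planted_module_sizes: tuple[int, ...] = (25, 25)
    planted_trait_r: float = -0.7
    n_template_nodes: int = 12
    perturbation_sd_case: float = 0.6
    perturbation_sd_control: float = 0.4
    n_genes: int = 200
    chrom_length: int = 10_000_000
    enriched_set_size: int = 20

    def validate(self) -> "SimulationConfig":
        positive = (
            "n_case", "n_control", "n_annotations",
            "variants_per_participant_mean", "effect_annotation_count",
            "n_template_nodes", "perturbation_sd_case",
            "perturbation_sd_control", "n_genes", "chrom_length",
            "enriched_set_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not -1.0 < self.planted_trait_r < 1.0:
            raise ConfigurationError("planted_trait_r must lie in (-1, 1)")
        if self.tail_inflation < 1.0:
            raise ConfigurationError("tail_inflation must be >= 1")
        if any(m < 2 for m in self.planted_module_sizes):
            raise ConfigurationError("planted module sizes must be >= 2")
        if self.effect_annotation_count > self.n_annotations:
            raise ConfigurationError(
                "effect_annotation_count exceeds n_annotations")
        if sum(self.planted_module_sizes) + self.effect_annotation_count \
                > self.n_annotations:
            raise ConfigurationError(
                "planted modules plus effect annotations exceed the "
                "annotation count")
        return self


@dataclass
class FeatureWeights:
    """Feature weights and Gaussian kernel scales for node similarity.

    Weights must sum to one.  The sigma values are the kernel scales of
    the per-feature similarity ``exp(-d^2 / (2 sigma^2))``; position and
    depth are in mm, area in mm^2, topology is unitless.
    """

    w_position: float = 0.25
    w_depth: float = 0.25
    w_area: float = 0.25
    w_topology: float = 0.25
    sigma_position: float = 15.0
    sigma_depth: float = 5.0
    sigma_area: float = 200.0
    sigma_topology: float = 2.0

    def validate(self) -> "FeatureWeights":
        weights = (self.w_position, self.w_depth, self.w_area,
                   self.w_topology)
        if any(w < 0 for w in weights):
            raise ConfigurationError("feature weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError("feature weights must sum to 1")
        for name in ("sigma_position", "sigma_depth", "sigma_area",
                     "sigma_topology"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        return self

    @classmethod
    def single_feature(cls, feature: str, **sigmas) -> "FeatureWeights":
        """All weight on one feature, the rest zeroed."""
        if feature not in ("position", "depth", "area", "topology"):
            raise ConfigurationError(f"unknown feature {feature!r}")
        kw = {f"w_{name}": (1.0 if name == feature else 0.0)
              for name in ("position", "depth", "area", "topology")}
        kw.update(sigmas)
        return cls(**kw).validate()


@dataclass
class NetworkParams:
    """Weighted-correlation-network construction parameters.

    ``deep_split`` is recorded for provenance only: module detection here
    uses a static dendrogram cut plus a minimum module size rather than
    the Dynamic Hybrid sensitivity heuristic.
    """

    power: int = 9
    network_type: str = "signed-hybrid"
    cut_height: float = 0.995
    deep_split: int = 2
    min_module_size: int = 20
    merge_height: float = 0.25
    scale_free_r2_target: float = 0.8

    def validate(self) -> "NetworkParams":
        if self.power < 1:
            raise ConfigurationError("power must be >= 1")
        if not 0.0 < self.cut_height <= 1.0:
            raise ConfigurationError("cut_height must lie in (0, 1]")
        if not 0.0 < self.merge_height <= 1.0:
            raise ConfigurationError("merge_height must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ConfigurationError("min_module_size must be >= 2")
        if self.network_type != "signed-hybrid":
            raise ConfigurationError("only signed-hybrid networks supported")
        return self


def dataclass_from_dict(cls, data: dict):
    """Build a parameter dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {', '.join(unknown)}")
    coerced = dict(data)
    if cls is SimulationConfig and "planted_module_sizes" in coerced:
        coerced["planted_module_sizes"] = tuple(
            coerced["planted_module_sizes"])
    obj = cls(**coerced)
    return obj.validate()
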