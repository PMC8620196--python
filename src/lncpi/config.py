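"""Aggregated run configuration with documented defaults.

Every tunable of the pipeline lives here: descriptor parameters
(k_gap=5, k_tuple=3), the number of selected features (k_features,
default 500 — always logged since results depend on it), the three
classifier configurations, the ensemble weights (0.4, 0.3, 0.3), the
hard-decision threshold (0.5), and the experiment shape (1:1 negative
sampling, 5 folds, 20 repeats). Values can be overridden from a flat
``key = value`` file with dotted keys, e.g. ``dnn.learning_rate = 0.001``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .classifiers import ClassifierConfig, DNNConfig, GBTConfig, SVMConfig
from .ensemble import EnsembleWeights
from .io_formats import read_config
from .sequence_features import DescriptorConfig


@dataclass(frozen=True)
class PipelineConfig:
    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    weights: EnsembleWeights = field(default_factory=EnsembleWeights)
    k_features: int = 500
    threshold: float = 0.5
    negative_ratio: float = 1.0
    n_folds: int = 5
    n_repeats: int = 20


_SECTIONS = {
    "descriptor": DescriptorConfig,
    "dnn": DNNConfig,
    "gbt": GBTConfig,
    "svm": SVMConfig,
    "weights": EnsembleWeights,
}


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    if isinstance(current, tuple):
        return tuple(int(x) for x in raw.replace(",", " ").split())
    return raw


def config_from_flat(flat: dict[str, str]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from dotted key/value overrides."""
    sections = {name: {} for name in _SECTIONS}
    top: dict[str, object] = {}
    base = PipelineConfig()
    for key, raw in flat.items():
        if "." in key:
            section, fieldname = key.split(".", 1)
            if section not in _SECTIONS:
                raise KeyError(f"unknown config section {section!r}")
            cls = _SECTIONS[section]
            defaults = cls()
            if not hasattr(defaults, fieldname):
                raise KeyError(f"unknown config key {key!r}")
            sections[section][fieldname] = _coerce(getattr(defaults, fieldname), raw)
        else:
            if not hasattr(base, key):
                raise KeyError(f"unknown config key {key!r}")
            top[key] = _coerce(getattr(base, key), raw)
    classifier = ClassifierConfig(
        dnn=DNNConfig(**sections["dnn"]),
        gbt=GBTConfig(**sections["gbt"]),
        svm=SVMConfig(**sections["svm"]),
    )
    return PipelineConfig(
        descriptor=DescriptorConfig(**sections["descriptor"]),
        classifier=classifier,
        weights=EnsembleWeights(**sections["weights"]),
        **top,
    )


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a flat config file; ``None`` yields pure defaults."""
    if path is None:
        return PipelineConfig()
    return config_from_flat(read_config(path))


def config_to_flat(config: PipelineConfig) -> dict[str, str]:
    """Flatten a config back to dotted key/value pairs (for manifests)."""
    flat: dict[str, str] = {}
    for name, sub in (
        ("descriptor", config.descriptor),
        ("dnn", config.classifier.dnn),
        ("gbt", config.classifier.gbt),
        ("svm", config.classifier.svm),
        ("weights", config.weights),
    ):
        for f in dataclasses.fields(sub):
            v = getattr(sub, f.name)
            flat[f"{name}.{f.name}"] = (
                " ".join(str(x) for x in v) if isinstance(v, tuple) else str(v)
            )
    for key in ("k_features", "threshold", "negative_ratio", "n_folds", "n_repeats"):
        flat[key] = str(getattr(config, key))
    return flat
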