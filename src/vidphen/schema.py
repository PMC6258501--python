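"""Behavioral feature vocabulary and per-classifier feature subsets.

Raters answer 30 multiple-choice behavioral items per video; each answer maps
to an ordinal severity score in {0,1,2,3} (higher = more severe autism-related
behavior) or the sentinel 8 when the behavior could not be scored from the
video.  Eight named classifiers each consume a declared subset of these
features; the union of the eight subsets has 23 distinct features, and the
remaining 7 "extra" features are scored by raters but used by no classifier in
the suite (they exist for the separate video-feature model).

The schema is data, not code: a default schema file ships with the package and
all pipeline logic is schema-agnostic.  Feature prompts in the default file
that the source instruments do not name publicly are documented placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

#: sentinel score meaning "feature could not be scored from this video"
UNSCORABLE = 8

#: answer label that maps to the unscorable sentinel
UNSCORABLE_LABEL = "unscorable"

#: valid ordinal scores (excluding the unscorable sentinel)
ORDINAL_SCORES = (0, 1, 2, 3)

#: classifier name -> required subset size ("model type"-"number of features")
EXPECTED_SUBSET_SIZES = {
    "ADTree7": 7,
    "ADTree8": 8,
    "SVM5": 5,
    "LR5": 5,
    "LR9": 9,
    "SVM12": 12,
    "SVM10": 10,
    "LR10": 10,
}

N_FEATURES = 30
N_MODEL_FEATURES = 23
N_EXTRA_FEATURES = 7


class SchemaError(ValueError):
    """A schema file violates a structural invariant."""


@dataclass(frozen=True)
class FeatureDefinition:
    """One behavioral item: its answer options and answer->score map."""

    feature_id: str
    display_name: str
    answer_options: tuple[str, ...]
    score_map: Mapping[str, int]
    allows_unscorable: bool = True

    def validate(self) -> None:
        missing = [a for a in self.answer_options if a not in self.score_map]
        if missing:
            raise SchemaError(
                f"feature {self.feature_id!r}: score_map not total over "
                f"answer_options (missing {missing})"
            )
        bad = {a: s for a, s in self.score_map.items() if s not in ORDINAL_SCORES}
        if bad:
            raise SchemaError(
                f"feature {self.feature_id!r}: scores outside {{0,1,2,3}}: {bad}"
            )
        if not self.allows_unscorable:
            raise SchemaError(
                f"feature {self.feature_id!r}: every feature must permit the "
                f"unscorable code {UNSCORABLE}"
            )


@dataclass(frozen=True)
class FeatureSchema:
    """The 30-feature vocabulary plus per-classifier feature subsets."""

    features: tuple[FeatureDefinition, ...]
    model_subsets: Mapping[str, tuple[str, ...]]
    extra_features: tuple[str, ...] = field(default_factory=tuple)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(f.feature_id for f in self.features)

    @property
    def model_feature_union(self) -> set[str]:
        out: set[str] = set()
        for subset in self.model_subsets.values():
            out.update(subset)
        return out

    def feature(self, feature_id: str) -> FeatureDefinition:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def validate(self) -> None:
        if len(self.features) != N_FEATURES:
            raise SchemaError(
                f"schema must declare exactly {N_FEATURES} features, "
                f"got {len(self.features)}"
            )
        ids = self.feature_ids
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate feature_ids in schema")
        for f in self.features:
            f.validate()
        declared = set(ids)
        for name, subset in self.model_subsets.items():
            unknown = [fid for fid in subset if fid not in declared]
            if unknown:
                raise SchemaError(
                    f"subset {name!r} references undeclared features {unknown}"
                )
            if len(set(subset)) != len(subset):
                raise SchemaError(f"subset {name!r} lists a feature twice")
            want = EXPECTED_SUBSET_SIZES.get(name)
            if want is not None and len(subset) != want:
                raise SchemaError(
                    f"subset {name!r} must have {want} features, got {len(subset)}"
                )
        missing_models = set(EXPECTED_SUBSET_SIZES) - set(self.model_subsets)
        if missing_models:
            raise SchemaError(f"missing model subsets: {sorted(missing_models)}")
        union = self.model_feature_union
        if len(union) != N_MODEL_FEATURES:
            raise SchemaError(
                f"union of model subsets must have {N_MODEL_FEATURES} distinct "
                f"features, got {len(union)}"
            )
        extras = set(self.extra_features)
        if len(extras) != N_EXTRA_FEATURES or len(self.extra_features) != N_EXTRA_FEATURES:
            raise SchemaError(
                f"exactly {N_EXTRA_FEATURES} extra features required, "
                f"got {len(self.extra_features)}"
            )
        if extras & union:
            raise SchemaError(
                f"extra features overlap model subsets: {sorted(extras & union)}"
            )
        if not extras <= declared:
            raise SchemaError("extra features reference undeclared features")
        if union | extras != declared:
            raise SchemaError(
                "model subsets plus extras must cover all 30 features"
            )


def _parse_schema_dict(raw: Mapping) -> FeatureSchema:
    try:
        feature_items = raw["features"]
        subsets = raw["model_subsets"]
        extras = raw.get("extra_features", [])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"schema file missing required key: {exc}") from exc
    features = []
    for item in feature_items:
        try:
            features.append(
                FeatureDefinition(
                    feature_id=item["id"],
                    display_name=item.get("name", item["id"]),
                    answer_options=tuple(item["options"]),
                    score_map={str(k): int(v) for k, v in item["scores"].items()},
                    allows_unscorable=bool(item.get("allows_unscorable", True)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed feature entry {item!r}: {exc}") from exc
    schema = FeatureSchema(
        features=tuple(features),
        model_subsets={k: tuple(v) for k, v in subsets.items()},
        extra_features=tuple(extras),
    )
    schema.validate()
    return schema


def load_schema(path: str | Path | None = None) -> FeatureSchema:
    """Load and validate a schema file; ``None`` loads the bundled default."""
    if path is None:
        text = (
            resources.files("vidphen").joinpath("data/default_schema.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise SchemaError(f"schema file does not parse{line}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise SchemaError("schema file must contain a mapping at top level")
    return _parse_schema_dict(raw)


def save_schema(schema: FeatureSchema, path: str | Path) -> None:
    """Write a schema to YAML such that load_schema round-trips it exactly."""
    raw = {
        "features": [
            {
                "id": f.feature_id,
                "name": f.display_name,
                "options": list(f.answer_options),
                "scores": {a: int(f.score_map[a]) for a in f.answer_options},
                "allows_unscorable": f.allows_unscorable,
            }
            for f in schema.features
        ],
        "model_subsets": {k: list(v) for k, v in schema.model_subsets.items()},
        "extra_features": list(schema.extra_features),
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def map_answer_to_score(feature: FeatureDefinition, answer: str) -> int:
    """Map an answer label to its ordinal score; the unscorable label maps to 8."""
    if answer == UNSCORABLE_LABEL:
        return UNSCORABLE
    try:
        return feature.score_map[answer]
    except KeyError:
        raise ValueError(
            f"unknown answer {answer!r} for feature {feature.feature_id!r}; "
            f"options are {list(feature.answer_options)} or {UNSCORABLE_LABEL!r}"
        ) from None


def project_vector(
    schema: FeatureSchema,
    record: Mapping[str, int],
    model_name: str,
):
    """Restrict a 30-score record to the named model's subset, in subset order."""
    import numpy as np

    if model_name not in schema.model_subsets:
        raise KeyError(
            f"unknown model {model_name!r}; known: {sorted(schema.model_subsets)}"
        )
    subset = schema.model_subsets[model_name]
    return np.asarray([record[fid] for fid in subset], dtype=float)
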