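"""Analysis configuration.

All thresholds used by the screening and SGA pipelines live in one
:class:`ScreenConfig` object so that a whole analysis is reproducible from a
single small YAML/JSON file.  Defaults are the values used throughout the
fission-yeast chemogenomic workflow this package implements: fitness-ratio
cutoffs 1.35 / 0.65, a 30 kb linkage-exclusion window, a 50 px minimum
control colony size and symmetric interaction-score cutoffs of +/-15 on the
100 x log10 scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

_REPLICATE_STRATEGIES = ("pooled", "per-plate")
_MISSING_POLICIES = ("drop", "zero")


@dataclass
class ScreenConfig:
    """Thresholds and policies shared by the screen and SGA pipelines.

    Parameters
    ----------
    resistant_cutoff, sensitive_cutoff
        Fitness-ratio cutoffs: a strain is called resistant when its ratio is
        strictly above ``resistant_cutoff`` and sensitive when strictly below
        ``sensitive_cutoff``.
    linkage_window_bp
        Library mutants within this distance (inclusive) of a query locus on
        the same chromosome are excluded from SGA scoring.
    min_control_colony_px
        Library genes whose control-array double-mutant median colony size is
        strictly below this value (raw pixels) are excluded.
    interaction_cutoff
        Symmetric bound on the interaction score: negative below
        ``-interaction_cutoff``, positive above ``+interaction_cutoff``.
    score_scale
        Multiplier applied to log10 colony-size ratios to form interaction
        scores; 100 makes the +/-15 cutoffs correspond to a ~1.41-fold change.
    cv_max
        Maximum allowed coefficient of variation across replicate spots.
    control_missing_policy
        How missing colonies on control plates enter medians: ``"drop"``
        (ignore them) or ``"zero"`` (count them as zero-size colonies).
    normalize_plates
        Whether fitness ratios are computed on plate-median-normalized sizes
        (default) or raw medians.
    replicate_strategy
        ``"pooled"`` takes one median over all replicate spots; ``"per-plate"``
        takes per-plate medians first and then the median of those.
    """

    resistant_cutoff: float = 1.35
    sensitive_cutoff: float = 0.65
    linkage_window_bp: int = 30_000
    min_control_colony_px: float = 50.0
    interaction_cutoff: float = 15.0
    score_scale: float = 100.0
    cv_max: float = 0.5
    control_missing_policy: str = "drop"
    normalize_plates: bool = True
    replicate_strategy: str = "pooled"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.sensitive_cutoff < 1.0 < self.resistant_cutoff):
            raise ValueError(
                "cutoffs must satisfy sensitive_cutoff < 1 < resistant_cutoff; "
                f"got sensitive={self.sensitive_cutoff}, resistant={self.resistant_cutoff}"
            )
        for name in (
            "resistant_cutoff",
            "sensitive_cutoff",
            "linkage_window_bp",
            "min_control_colony_px",
            "interaction_cutoff",
            "score_scale",
            "cv_max",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if self.replicate_strategy not in _REPLICATE_STRATEGIES:
            raise ValueError(
                f"replicate_strategy must be one of {_REPLICATE_STRATEGIES}, "
                f"got {self.replicate_strategy!r}"
            )
        if self.control_missing_policy not in _MISSING_POLICIES:
            raise ValueError(
                f"control_missing_policy must be one of {_MISSING_POLICIES}, "
                f"got {self.control_missing_policy!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path | None = None, **overrides) -> ScreenConfig:
    """Load a :class:`ScreenConfig` from a YAML or JSON file.

    Absent keys fall back to defaults; unknown keys raise a warning and are
    ignored; invariant violations raise ``ValueError``.  Keyword overrides are
    applied on top of the file.  The effective values are logged.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a key/value mapping")
        values.update(loaded)
    values.update(overrides)

    known = {f.name for f in fields(ScreenConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        warnings.warn(
            f"ignoring unknown config keys: {', '.join(unknown)}", stacklevel=2
        )
    kwargs = {k: v for k, v in values.items() if k in known}
    config = ScreenConfig(**kwargs)
    for field in fields(ScreenConfig):
        source = "file/override" if field.name in kwargs else "default"
        logger.debug("config %s = %r (%s)", field.name, getattr(config, field.name), source)
    return config
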