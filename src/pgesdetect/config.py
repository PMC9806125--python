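"""Pipeline configuration: one JSON-serializable object carrying every
tunable of the detector, so a run is reproducible from its manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .classify import DEFAULT_BOOST, DEFAULT_CONF_THRESH, DEFAULT_MIN_RUN, RFParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All detector knobs.

    ``emd_band`` feeds the EMD/Hilbert features, ``baseline_band`` the
    time/frequency/wavelet/correlation features.  ``K`` is the number of
    artifact clusters (7 by default), ``boost`` the sample-weight
    multiplier for the focal cluster's epochs.
    """

    emd_band: tuple[float, float] = (0.5, 30.0)
    baseline_band: tuple[float, float] = (0.5, 5.0)
    epoch_length: float = 1.0
    postictal_duration: float = 300.0
    map_T: int = 300
    K: int = 7
    boost: float = DEFAULT_BOOST
    rf_trees: int = 100
    rf_max_depth: int | None = None
    min_run: int = DEFAULT_MIN_RUN
    conf_thresh: float = DEFAULT_CONF_THRESH
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            "epoch_length": self.epoch_length,
            "postictal_duration": self.postictal_duration,
            "map_T": self.map_T,
            "K": self.K,
            "boost": self.boost,
            "rf_trees": self.rf_trees,
            "min_run": self.min_run,
            "conf_thresh": self.conf_thresh,
        }
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive (got {value})")

    @property
    def rf_params(self) -> RFParams:
        return RFParams(
            n_trees=self.rf_trees, max_depth=self.rf_max_depth, seed=self.seed
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["emd_band"] = list(self.emd_band)
        d["baseline_band"] = list(self.baseline_band)
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d["emd_band"] = tuple(d.get("emd_band", (0.5, 30.0)))
        d["baseline_band"] = tuple(d.get("baseline_band", (0.5, 5.0)))
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
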