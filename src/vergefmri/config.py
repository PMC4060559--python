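"""Pipeline configuration with validation.

Defaults equal the study's printed acquisition/analysis parameters: 200 Hz
eye-movement sampling, TR 2 s, 5 dropped volumes, 0.01-0.15 Hz band-pass,
r >= 0.4 correlation threshold, 99%/97% CSF/WM probability thresholds, and
5 principal components per tissue.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    sample_rate_hz: float = 200.0
    tr_s: float = 2.0
    n_drop: int = 5
    band_hz: tuple[float, float] = (0.01, 0.15)
    r_thresh: float = 0.4
    csf_thresh: float = 0.99
    wm_thresh: float = 0.97
    n_pcs: int = 5
    hemodynamic_shift_s: float = 4.0
    saccade_ratio: float = 5.0
    saccade_floor_deg_s: float = 40.0
    peak_window_s: float = 2.0
    device_range_deg: float = 25.0
    equal_variance_ttest: bool = True
    bonferroni: bool = False

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty list means valid)."""
        errors: list[str] = []
        if self.sample_rate_hz <= 0:
            errors.append("sample_rate_hz must be positive")
        if self.tr_s <= 0:
            errors.append("tr_s must be positive")
        if self.n_drop < 0:
            errors.append("n_drop must be >= 0")
        low, high = self.band_hz
        if not 0 <= low < high:
            errors.append("band_hz must satisfy 0 <= low < high")
        elif self.tr_s > 0 and high > 1.0 / (2.0 * self.tr_s) + 1e-12:
            errors.append("band_hz high cutoff exceeds the Nyquist frequency")
        if not -1.0 <= self.r_thresh <= 1.0:
            errors.append("r_thresh must lie in [-1, 1]")
        for name in ("csf_thresh", "wm_thresh"):
            if not 0.0 < getattr(self, name) <= 1.0:
                errors.append(f"{name} must lie in (0, 1]")
        if self.n_pcs < 1:
            errors.append("n_pcs must be >= 1")
        if self.hemodynamic_shift_s < 0:
            errors.append("hemodynamic_shift_s must be >= 0")
        if self.saccade_ratio <= 0 or self.saccade_floor_deg_s <= 0:
            errors.append("saccade thresholds must be positive")
        if self.peak_window_s <= 0:
            errors.append("peak_window_s must be positive")
        return errors

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if k == "band_hz" else v for k, v in d.items()})
        errors = cfg.validate()
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Functional alias for :meth:`PipelineConfig.validate`."""
    return config.validate()
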