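"""Per-assay configuration with documented defaults.

The configuration file is plain text, one ``assay.key = value`` per line
(``#`` comments allowed).  Unknown assay or key names are rejected so typos
never silently fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path

from .errors import ValidationError

#: Every tunable parameter with its default.  Values are floats, ints, bools
#: or strings; lists are comma-separated in the file.
DEFAULTS: dict[str, dict[str, object]] = {
    "msd": {
        "dt_s": 0.01,               # frame interval (100 fps regime)
        "max_lag_fraction": 0.25,   # variance control at long lags
        "max_disp_um": 0.0,         # 0 -> auto: 5x median frame step
        "min_mass": 0.0,
        "pixel_size_um": 1.0,
    },
    "fret": {
        "donor_window_nm": "470,490",
        "acceptor_window_nm": "520,540",
        "background_label": 0,      # 0 -> no subtraction
        "per_pixel": False,
    },
    "flim": {
        "min_photons": 100,
        "per_pixel": False,
    },
    "eop": {
        "mode": "auto",             # "polygon" | "skeleton" | "auto"
        "report_excess": False,     # also emit eop - 1
    },
    "polarity": {
        "quantile": 0.80,
        "grid_shape": "64,64",
        "min_mask_px": 20,
    },
    "ncratio": {
        "background": "auto",       # "auto" -> median outside cell mask
    },
    "dots": {
        "min_distance_px": 3,
        "threshold": "otsu",
    },
    "facount": {
        "min_area_um2": 0.25,
        "threshold": "otsu",
    },
    "coherency": {
        "tensor_sigma_px": 2.0,
    },
    "spreading": {},
    "motility": {
        "frame_interval_min": 10.0,
        "max_disp_um": 50.0,
        "min_track_length": 12,
        "smooth_sigma_px": 5.0,
        "pixel_size_um": 1.0,
    },
    "simulate": {
        "seed": 0,
    },
}


class AssayConfig:
    """Validated key-value parameter store with per-assay defaults."""

    def __init__(self, overrides: dict[str, dict[str, object]] | None = None):
        self._values = {assay: dict(params) for assay, params in DEFAULTS.items()}
        for assay, params in (overrides or {}).items():
            for key, value in params.items():
                self.set(assay, key, value)

    @classmethod
    def from_file(cls, path: str | Path) -> "AssayConfig":
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line or "." not in line.split("=", 1)[0]:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'assay.key = value', got {raw!r}"
                )
            dotted, _, value = line.partition("=")
            assay, _, key = dotted.strip().partition(".")
            cfg.set(assay, key, value.strip())
        return cfg

    def set(self, assay: str, key: str, value: object) -> None:
        if assay not in self._values:
            raise ValidationError(f"unknown assay {assay!r}")
        if key not in self._values[assay]:
            raise ValidationError(f"unknown parameter {assay}.{key}")
        default = DEFAULTS[assay][key]
        if isinstance(value, str) and not isinstance(default, str):
            if isinstance(default, bool):
                value = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                value = int(value)
            elif isinstance(default, float):
                value = float(value)
        self._values[assay][key] = value

    def get(self, assay: str, key: str):
        if assay not in self._values or key not in self._values[assay]:
            raise ValidationError(f"unknown parameter {assay}.{key}")
        return self._values[assay][key]

    def section(self, assay: str) -> dict[str, object]:
        if assay not in self._values:
            raise ValidationError(f"unknown assay {assay!r}")
        return dict(self._values[assay])
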