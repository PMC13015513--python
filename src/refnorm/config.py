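"""Run configuration with flag > config-file > default precedence.

The config file is a flat YAML mapping of scalars (a simple ``key: value``
text format). Unknown keys are an error with a close-match suggestion;
values are coerced to the default's type, and a mismatch names the key and
the expected type. The resolved configuration (with per-key provenance) is
echoed into every output directory as ``run_config.resolved``.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "resolve_config"]

# fields that may be None (optional overrides); mapped to their scalar type
_OPTIONAL_FLOAT = ("sfbg", "sfsig", "alpha", "beta", "noise", "single_factor")
_OPTIONAL_INT = ("seed",)


@dataclass
class RunConfig:
    """All tunables of the normalization and differential stages.

    Units: window sizes in bp; scale factors in track units; ``alpha`` and
    ``beta`` in log2 space; ``noise`` in track units; ``pseudocount`` in
    track units added before every log2.
    """

    # --- binning and windows ---
    bin_size: int = 50             # genome tiling for classification and output
    profile_bin: int = 25          # bin width inside reference profile windows
    flank: int = 1000              # default extract_signal half-window
    n_bins: int = 40               # default extract_signal bin count
    signal_halfwidth: int = 200    # central signal window = center +/- this
    bg_inner: int = 2000           # background flank starts here (bp from center)
    bg_outer: int = 4000           # background flank ends here
    # --- estimation ---
    pseudocount: float = 1.0
    chi2_quantile: float = 0.99
    second_pass: bool = False      # re-estimate Mahalanobis stats after removal
    background_subtract: bool = True
    # --- mode and parameter overrides (None = estimate) ---
    mode: str = "two-tier"         # two-tier | background-only | single-factor
    sfbg: float | None = None
    sfsig: float | None = None
    alpha: float | None = None
    beta: float | None = None
    noise: float | None = None
    single_factor: float | None = None
    # --- differential stage ---
    stat: str = "fc"               # fc | poisson | both
    fc_cutoff: float = 2.0
    q: float = 0.05
    adjust: bool = True            # Benjamini-Hochberg in Poisson mode
    exposure_ratio: float = 1.0
    pseudo_floor: float = 1.0
    # --- misc ---
    make_plots: bool = True
    seed: int | None = None
    source: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name != "source":
                self.source.setdefault(f.name, "default")

    def write_resolved(self, path: str | Path) -> None:
        """Echo the resolved configuration with per-key provenance."""
        with open(path, "w") as fh:
            for f in fields(self):
                if f.name == "source":
                    continue
                value = getattr(self, f.name)
                fh.write(f"{f.name}: {value}  # {self.source.get(f.name, 'default')}\n")


def _coerce(key: str, value, default_value):
    """Coerce a raw config value to the type implied by the default."""
    if value is None:
        return None
    if key in _OPTIONAL_FLOAT:
        target = float
    elif key in _OPTIONAL_INT:
        target = int
    else:
        target = type(default_value)
    if target is bool:
        if isinstance(value, bool):
            return value
        if isinstance(value, str) and value.lower() in ("true", "false", "yes", "no"):
            return value.lower() in ("true", "yes")
        raise ConfigError(f"config key {key!r}: expected bool, got {value!r}")
    if target is int:
        if isinstance(value, bool) or (not isinstance(value, int)
                                       and not (isinstance(value, str) and value.lstrip("-").isdigit())):
            raise ConfigError(f"config key {key!r}: expected int, got {value!r}")
        return int(value)
    if target is float:
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ConfigError(f"config key {key!r}: expected float, got {value!r}") from None
    if target is str:
        return str(value)
    return value  # pragma: no cover


def resolve_config(defaults: RunConfig | None = None,
                   config_file: str | Path | None = None,
                   flags: dict | None = None) -> RunConfig:
    """Merge defaults, a config file, and explicit flags (highest precedence).

    ``flags`` holds only keys the user actually set. Unknown keys raise
    :class:`ConfigError` with a suggestion when a close match exists.
    """
    cfg = defaults or RunConfig()
    valid = {f.name for f in fields(cfg)} - {"source"}

    def apply(layer: dict, origin: str) -> None:
        for key, value in layer.items():
            if key not in valid:
                hint = difflib.get_close_matches(key, valid, n=1)
                suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ConfigError(f"unknown config key {key!r}{suggestion}")
            default_value = RunConfig.__dataclass_fields__[key].default
            setattr(cfg, key, _coerce(key, value, default_value))
            cfg.source[key] = origin

    if config_file is not None:
        path = Path(config_file)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            loaded = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse config file {path}: {exc}") from exc
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a flat key: value mapping")
        apply(loaded, "config-file")
    if flags:
        apply(flags, "flag")
    return cfg
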