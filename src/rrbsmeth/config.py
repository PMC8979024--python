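"""Flat key=value configuration shared by every pipeline stage.

Every threshold used anywhere in the package is a named key with its default
recorded here, so a complete parameter set can be serialized next to the
results it produced and re-loaded bit-for-bit.  The file format is one
``key = value`` pair per line; ``#`` starts a comment; values are coerced to
the type of the corresponding default.
"""

from __future__ import annotations

import logging
from pathlib import Path

log = logging.getLogger("rrbsmeth")

DEFAULTS: dict[str, object] = {
    # methylation calling
    "conversion_error_rate": 0.005,   # bisulfite non-conversion background
    "fdr_alpha": 0.05,                # BH threshold on per-site q-values
    "level_weighting": "read_weighted",  # or "site_mean"
    # metagene profiling
    "flank_bp": 2000,
    "flank_bins": 20,
    "body_bins": 40,
    # DMR criteria; "min" bounds are strict (count must exceed them)
    "dmr_max_gap": 200,        # adjacent methylated sites must be < this apart
    "dmr_min_mc": 5,           # methylated cytosines per region, > in >=1 sample
    "dmr_min_cov": 10,         # reads per member cytosine, > in both samples
    "dmr_min_meth_reads": 4,   # reads per methylated member cytosine, >
    "dmr_min_len": 40,         # inclusive
    "dmr_max_len": 10000,      # inclusive
    "dmr_min_fold": 2.0,       # strict >
    "dmr_max_p": 0.05,         # inclusive <=
    # DMP definition (per-site analogue of the DMR criteria)
    "dmp_min_cov": 10,         # strict > in both samples
    "dmp_min_delta": 0.1,      # |level difference| >=
    "dmp_max_p": 0.05,         # two-sided Fisher exact, inclusive <=
    # expression integration
    "deg_fdr_threshold": 0.05,  # strict <
    "zero_expression_cutoff": 0.0,
    # logos
    "logo_window": 10,
    "ic_small_sample_correction": False,
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Return the default configuration, updated from ``path`` then ``overrides``.

    Unknown keys raise ``KeyError`` (typo safety); values from file are coerced
    to the type of the default they replace.
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cfg:
                raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
            cfg[key] = _coerce(value, cfg[key])
    if overrides:
        for key, value in overrides.items():
            if key not in cfg:
                raise KeyError(f"unknown config key {key!r}")
            cfg[key] = value
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    lines = [f"{key} = {cfg[key]}" for key in sorted(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce(text: str, default: object):
    if isinstance(default, bool):
        low = text.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean from {text!r}")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float):
        return float(text)
    return text


def log_filter(stage: str, n_in: int, n_out: int) -> None:
    """Audit helper: every filtering stage reports records in/out."""
    log.info("%s: %d -> %d records", stage, n_in, n_out)
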