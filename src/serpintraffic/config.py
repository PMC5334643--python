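"""Plain-text configuration dialect shared by all pipeline stages.

INI-style sections and ``key = value`` pairs (parsed with
:mod:`configparser`).  The schema is strict: unknown sections or keys are
errors naming the offending entry, so typos fail fast.  Values are scalars,
or comma-separated lists for grid keys.

Recognized sections and keys::

    [pipeline]   stages (comma list of: aggregate, vesicle, spots)
    [lattice]    Lx, Ly, Lz
    [rates]      k_in, k_out, k_D, k_H, k_R, k_E, k_K, k_f, k_A, k_L
    [run]        t_max, record_every, min_size
    [sweep]      kout_values, replicates, t_obs, min_size
    [membrane]   N_m, K_m, bond_stiffness
    [scaffold]   ratio, K_s, scaffold_bond
    [coupling]   eps_LJ, sigma, r_cut, eps_excluded, sigma_excluded,
                 cap_nodes, sigma_cap
    [protocol]   theta_s_target, ramp_steps, hold_steps, dt, gamma,
                 record_every
    [grid]       km_over_ks, eps_over_ks, N_m
    [spots]      n_images, n_nuclei, spots_per_cell, psf_sigma_px, snr,
                 image_size, scale, threshold, min_px, min_nucleus_area
"""

from __future__ import annotations

import configparser
from pathlib import Path

SCHEMA: dict[str, set[str]] = {
    "pipeline": {"stages"},
    "lattice": {"Lx", "Ly", "Lz"},
    "rates": {"k_in", "k_out", "k_D", "k_H", "k_R", "k_E", "k_K", "k_f", "k_A", "k_L"},
    "run": {"t_max", "record_every", "min_size"},
    "sweep": {"kout_values", "replicates", "t_obs", "min_size"},
    "membrane": {"N_m", "K_m", "bond_stiffness"},
    "scaffold": {"ratio", "K_s", "scaffold_bond"},
    "coupling": {
        "eps_LJ",
        "sigma",
        "r_cut",
        "eps_excluded",
        "sigma_excluded",
        "cap_nodes",
        "sigma_cap",
    },
    "protocol": {"theta_s_target", "ramp_steps", "hold_steps", "dt", "gamma", "record_every"},
    "grid": {"km_over_ks", "eps_over_ks", "N_m"},
    "spots": {
        "n_images",
        "n_nuclei",
        "spots_per_cell",
        "psf_sigma_px",
        "snr",
        "image_size",
        "scale",
        "threshold",
        "min_px",
        "min_nucleus_area",
    },
}

_INT_KEYS = {
    "Lx", "Ly", "Lz", "min_size", "replicates", "N_m", "ratio", "cap_nodes",
    "ramp_steps", "hold_steps", "n_images", "n_nuclei", "scale", "min_px",
    "min_nucleus_area", "image_size",
}
_LIST_KEYS = {"kout_values", "km_over_ks", "eps_over_ks", "stages"}


class ConfigError(ValueError):
    """Schema violation or unreadable configuration file."""


def _convert(key: str, raw: str):
    raw = raw.strip()
    if key in _LIST_KEYS:
        items = [x.strip() for x in raw.split(",") if x.strip()]
        if key == "stages":
            return items
        return [float(x) for x in items]
    if key in _INT_KEYS:
        return int(raw)
    return float(raw)


def load_config(path) -> dict[str, dict]:
    """Parse and schema-validate a configuration file into nested dicts."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    out: dict[str, dict] = {}
    for section in parser.sections():
        if section not in SCHEMA:
            raise ConfigError(f"unknown section [{section}] in {path}")
        out[section] = {}
        for key, raw in parser.items(section):
            # configparser lower-cases keys; recover canonical spelling
            canonical = {k.lower(): k for k in SCHEMA[section]}.get(key)
            if canonical is None:
                raise ConfigError(f"unknown key '{key}' in section [{section}] of {path}")
            try:
                out[section][canonical] = _convert(canonical, raw)
            except ValueError as exc:
                raise ConfigError(
                    f"bad value for '{key}' in section [{section}] of {path}: {raw!r}"
                ) from exc
    return out
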