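"""Run configuration and the XsTables file format.

Tables are stored as plain text: a JSON header (medium, grids, model
parameters, code version) followed by named array blocks in repr-exact
decimal, so write -> read round-trips bit-exactly.  Truncated or
mislabeled files raise explicit parse errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import yaml

from .tables import XsTables

__all__ = ["RunConfig", "write_xs_tables", "read_xs_tables"]

FORMAT_VERSION = 1

_ARRAYS = ["e_grid", "ek_grid", "ek_cdf", "binding_mean", "cos_nodes",
           "theta_cdf", "exc_weights", "exc_w_ev", "elastic_x",
           "elastic_theta"]


@dataclass
class RunConfig:
    """Configuration of one simulation run; defaults reproduce the
    reference transport model."""

    mode: str = "sp"                  # xs | sp | range | imfp | celldose
    medium: str = "water"
    energy_kev: float | None = None
    grid_kev: list | None = None
    histories: int = 10_000
    seed: int = 1
    tables_path: str | None = None
    # model switches
    n_e: int = 16
    theta_cut_lab_mrad: float = 0.1
    h0_screening: tuple = (0.35, 2.0)
    range_correction_um: float = 0.322
    nucleus_medium: str = "dna"
    cosine_source: bool = False
    transport_electrons: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["h0_screening"] = list(d["h0_screening"])
        return d


def _fmt_array(name: str, arr: np.ndarray) -> str:
    flat = np.asarray(arr, dtype=float).ravel()
    shape = ",".join(str(s) for s in np.asarray(arr).shape)
    body = "\n".join(repr(float(v)) for v in flat)
    return f"@array {name} shape={shape}\n{body}\n"


def write_xs_tables(tab: XsTables, path: str) -> None:
    header = dict(format_version=FORMAT_VERSION, medium=tab.medium,
                  density=tab.density, molar_mass=tab.molar_mass,
                  elastic_mass=tab.elastic_mass, meta=tab.meta,
                  tcs_keys=[[sp, pr] for (sp, pr) in tab.tcs])
    lines = ["#protrack-xs " + json.dumps(header, sort_keys=True)]
    for name in _ARRAYS:
        arr = getattr(tab, name)
        lines.append(_fmt_array(name, arr))
    for (sp, pr), arr in tab.tcs.items():
        lines.append(_fmt_array(f"tcs:{sp}:{pr}", arr))
    lines.append("@end\n")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_xs_tables(path: str) -> XsTables:
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#protrack-xs "):
        raise ValueError(f"{path}: not an XsTables file")
    header = json.loads(lines[0][len("#protrack-xs "):])
    if header.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format version "
                         f"{header.get('format_version')}")
    if lines[-1].strip() != "@end" and "@end" not in text:
        raise ValueError(f"{path}: truncated file (missing @end)")

    arrays = {}
    i = 1
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line == "@end":
            break
        if not line:
            i += 1
            continue
        if not line.startswith("@array "):
            raise ValueError(f"{path}: parse error at line {i + 1}")
        _, name, shape_s = line.split(" ", 2)
        shape = tuple(int(s) for s in
                      shape_s.removeprefix("shape=").split(","))
        count = int(np.prod(shape)) if shape else 1
        if i + count >= n + 1:
            raise ValueError(f"{path}: truncated array {name}")
        vals = np.array([float(lines[i + 1 + j]) for j in range(count)])
        arrays[name] = vals.reshape(shape)
        i += 1 + count
    else:
        raise ValueError(f"{path}: truncated file (missing @end)")

    tab = XsTables(medium=header["medium"], density=header["density"],
                   molar_mass=header["molar_mass"],
                   e_grid=arrays["e_grid"])
    for name in _ARRAYS:
        if name == "e_grid":
            continue
        if name not in arrays:
            raise ValueError(f"{path}: missing array {name}")
        setattr(tab, name, arrays[name])
    tab.tcs = {}
    for sp, pr in header["tcs_keys"]:
        key = f"tcs:{sp}:{pr}"
        if key not in arrays:
            raise ValueError(f"{path}: missing array {key}")
        tab.tcs[(sp, pr)] = arrays[key]
    tab.elastic_mass = header.get("elastic_mass", 18.015)
    tab.meta = header.get("meta", {})
    return tab
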