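"""Configuration, fixtures and plain-text artifact formats.

Every artifact file starts with a ``#``-prefixed JSON header carrying the
resolved configuration and seeds, so any output can be reproduced from its
own header.  Patterns use a one-line-per-time format: the divergence time
followed by 14 characters of 0/1 ordered by the binary hybrid label.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .dmi import DMITimeSeries
from .evolution import EvoParams, TabularLandscape, Trajectory
from .gpmap import Genome, ModelParams
from .speciation import HybridPattern

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "load_config",
    "dump_config",
    "Fixture",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_patterns",
    "read_patterns",
    "write_series",
    "read_series",
    "write_trajectory",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


_PROTOCOL_FIELDS = {
    "n_burn": 100_000,
    "n_gap": 100,
    "n_replicates": 10,
    "t_max": 10.0,
    "seed": None,
}


@dataclass
class ExperimentConfig:
    """Model + evolution parameters plus the divergence protocol."""

    model: ModelParams = field(default_factory=ModelParams)
    evo: EvoParams = field(default_factory=EvoParams)
    n_burn: int = 100_000
    n_gap: int = 100
    n_replicates: int = 10
    t_max: float = 10.0
    seed: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d or {})
        model_kw = dict(d.pop("model", {}))
        evo_kw = dict(d.pop("evo", {}))
        proto = {}
        model_names = {f.name for f in fields(ModelParams)}
        evo_names = {f.name for f in fields(EvoParams)}
        for key in list(d):
            if key in _PROTOCOL_FIELDS:
                proto[key] = d.pop(key)
            elif key in model_names:
                model_kw[key] = d.pop(key)
            elif key in evo_names:
                evo_kw[key] = d.pop(key)
        if d:
            raise ConfigError(f"unknown config field(s): {sorted(d)}")
        for kw, names, label in ((model_kw, model_names, "model"),
                                 (evo_kw, evo_names, "evo")):
            bad = set(kw) - names
            if bad:
                raise ConfigError(f"unknown {label} field(s): {sorted(bad)}")
        try:
            model = ModelParams(**model_kw)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"model: {e}") from None
        try:
            evo = EvoParams(**evo_kw)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"evo: {e}") from None
        return cls(model=model, evo=evo, **proto)

    def to_dict(self) -> dict:
        out = {
            "model": dataclasses.asdict(self.model),
            "evo": dataclasses.asdict(self.evo),
        }
        for name in _PROTOCOL_FIELDS:
            out[name] = getattr(self, name)
        return out


def load_config(path) -> ExperimentConfig:
    """Read a YAML (or JSON) config; defaults fill in, unknown keys reject."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return ExperimentConfig.from_dict(data)


def dump_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Fixtures: deterministic toy inputs used by tests, docs and the CLI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    name: str
    kind: str  # "pattern" | "landscape" | "parents"
    payload: object
    description: str


def _parent_pair_mc():
    """Synthetic viable parents whose M1 x C2 hybrid combinations fail.

    Both parents implement the same hand-designed patterning mechanism (R
    binds its own promoter with one mismatch, M binds its own B site
    perfectly and strongly stabilises R) but with complementary C-locus
    sequences, so hybrids pairing lineage-1 morphogen with the lineage-2
    regulatory region lose morphogen binding entirely.
    """
    p1 = Genome(g_R="00000", g_r="1000000000", g_M="00000",
                g_m="1111111111", g_P="0000000000", g_B="1111111111",
                alpha=10.0)
    p2 = Genome(g_R="00000", g_r="0111111111", g_M="00000",
                g_m="0000000000", g_P="1111111111", g_B="0000000000",
                alpha=10.0)
    return (p1, p2)


def _fixtures() -> dict:
    return {
        "fig4b": Fixture(
            "fig4b", "pattern",
            HybridPattern.from_labels(
                ["rmCa", "rMCa", "RmCa", "RMCa", "Rmca", "RMca"]),
            "six-hybrid pattern with three minimum covers of size 2 "
            "(n2 = 4/3, n3 = 2/3)"),
        "single_face": Fixture(
            "single_face", "pattern",
            HybridPattern.from_labels(["rmCa", "rMCa", "RmCa", "RMCa"]),
            "one full face: the pairwise DMI I_Ca"),
        "single_edge": Fixture(
            "single_edge", "pattern",
            HybridPattern.from_labels(["rmcA", "RmcA"]),
            "one edge: the 3-way DMI I_mcA"),
        "single_point": Fixture(
            "single_point", "pattern",
            HybridPattern.from_labels(["rmCA"]),
            "one isolated incompatible hybrid: the 4-way DMI I_rmCA"),
        "toy_two_site": Fixture(
            "toy_two_site", "landscape",
            TabularLandscape(log_fitness=(0.0, -0.1, -0.05, -0.2), n_sites=2),
            "explicit 4-genotype fitness table for the stationary-"
            "distribution oracle (use N = 10)"),
        "parent_pair_mc": Fixture(
            "parent_pair_mc", "parents", _parent_pair_mc(),
            "synthetic viable parent pair whose hybrids combining the "
            "lineage-1 morphogen with the lineage-2 cis-region are "
            "incompatible"),
    }


FIXTURE_NAMES = tuple(_fixtures())


def make_fixture(name: str) -> Fixture:
    """Deterministic named toy input; raises KeyError for unknown names."""
    try:
        return _fixtures()[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

def _write_header(fh, meta: dict) -> None:
    fh.write("# " + json.dumps(meta, default=str) + "\n")


def _read_header(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# "):
        try:
            return json.loads(first[2:])
        except json.JSONDecodeError:
            return {}
    return {}


def write_patterns(path, patterns, meta: dict | None = None) -> None:
    """Pattern exchange format: 'mu_t <tab> 14 chars of 0/1' per line."""
    with open(path, "w") as fh:
        _write_header(fh, meta or {})
        for p in patterns:
            fh.write(p.to_line() + "\n")


def read_patterns(path):
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            patterns.append(HybridPattern.from_line(line))
    return patterns


def write_series(path, series: DMITimeSeries, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta["n_replicates"] = series.n_replicates
    frame = series.to_frame()
    with open(path, "w") as fh:
        _write_header(fh, meta)
        frame.to_csv(fh, sep="\t", index=False)


def read_series(path) -> DMITimeSeries:
    meta = _read_header(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    keys = ("total", "2", "3", "4")
    mean = {k: frame[f"n{k}_mean"].to_numpy() for k in keys}
    sem = {k: frame[f"n{k}_sem"].to_numpy() for k in keys}
    pair = {c.removeprefix("I_"): frame[c].to_numpy()
            for c in frame.columns if c.startswith("I_")} or None
    return DMITimeSeries(mu_t=frame["mu_t"].to_numpy(),
                         n_replicates=int(meta.get("n_replicates", 1)),
                         mean=mean, sem=sem, pair_spectrum=pair)


def write_trajectory(path, traj: Trajectory, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.update({
        "initial_genome": traj.initial.to_dict(),
        "evo": dataclasses.asdict(traj.evo),
        "t0": traj.t0, "t_end": traj.t_end,
    })
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("time\tchannel\tsite\told\tnew\tdelta_F\tF_after\n")
        for ev in traj.events:
            fh.write(f"{ev.time:.10g}\t{ev.channel}\t{ev.site}\t{ev.old}"
                     f"\t{ev.new}\t{ev.delta_F:.10g}\t{ev.F_after:.10g}\n")
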