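"""YAML configuration parsing.

A config file has a ``system`` block describing the potential, plus
optional ``thermostat``, ``beads``, ``seeds`` and ``cutoffs`` blocks.
Example::

    system:
      kind: toywater3
      cutoff: 4.5
      params: {q_H: 0.41}
    thermostat: {friction_ps: 1.0, temperature: 300.0}
    beads: {P: 32}
    seeds: {main: 7}

Toy species that are not in the built-in mass table must be declared
under ``elements: {X: 1.0}``.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .potentials import (
    Harmonic1D,
    LJCoulombCluster,
    Morse1D,
    PeriodicPairFluid,
    LJPair,
    PotentialSurface,
    Quartic1D,
    ToyWater3,
)
from .units import register_element

_KINDS = {}


def _kind(name):
    def deco(fn):
        _KINDS[name] = fn
        return fn
    return deco


@_kind("harmonic1d")
def _mk_harm(block):
    return Harmonic1D(k=float(block.get("k", 2.0)))


@_kind("quartic1d")
def _mk_quart(block):
    return Quartic1D(c=float(block.get("c", 10.0)))


@_kind("morse1d")
def _mk_morse(block):
    return Morse1D(D=float(block.get("D", 400.0)), a=float(block.get("a", 2.0)))


@_kind("lj_coulomb_cluster")
def _mk_ljc(block):
    lj = {tuple(sorted(k.split("-"))): tuple(v) for k, v in (block.get("lj") or {}).items()}
    exclusions = {tuple(p) for p in (block.get("exclusions") or [])}
    return LJCoulombCluster(
        lj=lj, charges=block.get("charges") or {}, exclusions=exclusions
    )


@_kind("toywater3")
def _mk_tw(block):
    return ToyWater3(params=block.get("params"), cutoff=block.get("cutoff"))


@_kind("periodic_pair_fluid")
def _mk_fluid(block):
    pairs = {
        tuple(sorted(k.split("-"))): LJPair(*v) for k, v in (block.get("lj") or {}).items()
    }
    return PeriodicPairFluid(pairs=pairs, cutoff=float(block["cutoff"]))


def build_potential(block: dict) -> PotentialSurface:
    kind = block.get("kind")
    if kind not in _KINDS:
        raise KeyError(f"unknown potential kind {kind!r}; known: {sorted(_KINDS)}")
    return _KINDS[kind](block)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    for sym, mass in (cfg.get("elements") or {}).items():
        register_element(sym, float(mass))
    if "system" in cfg:
        cfg["potential"] = build_potential(cfg["system"])
    return cfg
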