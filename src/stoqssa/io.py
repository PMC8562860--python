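"""YAML network configs and tabular output writers.

The network config dialect (``schema: stoqssa-network/1``) is a direct
serialization of :class:`~stoqssa.ssa.ReactionNetwork`: species with
initial counts, reactions with mass-action factors and optional QSSA
terms, and declared conserved totals.  Numbers may use scientific
notation.  Every simulation run writes a JSON manifest (inputs, seed,
package version) next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from stoqssa.ssa import QssaTerm, Reaction, ReactionNetwork

SCHEMA = "stoqssa-network/1"

__all__ = ["network_to_dict", "network_from_dict", "save_network", "load_network",
           "write_manifest"]


def network_to_dict(net: ReactionNetwork) -> dict:
    d = {
        "schema": SCHEMA,
        "name": net.name,
        "species": list(net.species),
        "initial": {s: int(v) for s, v in net.initial.items()},
        "reactions": [],
        "conserved_totals": [
            {"name": n, "coefficients": dict(c), "value": int(v)}
            for n, c, v in net.conserved_totals
        ],
        "metadata": dict(net.metadata),
    }
    for r in net.reactions:
        rd = {
            "name": r.name,
            "changes": dict(r.changes),
            "rate": float(r.rate),
        }
        if r.reactants:
            rd["reactants"] = dict(r.reactants)
        if r.modifiers:
            rd["modifiers"] = dict(r.modifiers)
        if r.qssa is not None:
            q = r.qssa
            rd["qssa"] = {
                "total": q.total,
                "partner": q.partner,
                "K_d": q.K_d,
                "role": q.role,
                "estimator": q.estimator,
                "power": q.power,
                "pair_name": q.pair_name,
            }
        d["reactions"].append(rd)
    return d


def network_from_dict(d: dict) -> ReactionNetwork:
    if d.get("schema") != SCHEMA:
        raise ValueError(f"unsupported config schema {d.get('schema')!r}")
    reactions = []
    for rd in d["reactions"]:
        q = rd.get("qssa")
        term = None
        if q is not None:
            term = QssaTerm(
                total=q["total"],
                partner=q["partner"],
                K_d=float(q["K_d"]),
                role=q.get("role", "unbound"),
                estimator=q.get("estimator", "stqssa"),
                power=int(q.get("power", 1)),
                pair_name=q.get("pair_name", "pair"),
            )
        reactions.append(
            Reaction(
                name=rd["name"],
                changes={s: int(v) for s, v in rd["changes"].items()},
                rate=float(rd["rate"]),
                reactants={s: int(v) for s, v in rd.get("reactants", {}).items()},
                modifiers={s: int(v) for s, v in rd.get("modifiers", {}).items()},
                qssa=term,
            )
        )
    return ReactionNetwork(
        species=list(d["species"]),
        initial={s: int(v) for s, v in d["initial"].items()},
        reactions=reactions,
        conserved_totals=[
            (c["name"], {s: int(v) for s, v in c["coefficients"].items()},
             int(c["value"]))
            for c in d.get("conserved_totals", [])
        ],
        name=d.get("name", "network"),
        metadata=d.get("metadata", {}),
    )


def save_network(net: ReactionNetwork, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(network_to_dict(net), sort_keys=False))


def load_network(path: str | Path) -> ReactionNetwork:
    return network_from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(path: str | Path, **fields) -> None:
    from stoqssa import __version__

    payload = {"package": "stoqssa", "version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
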