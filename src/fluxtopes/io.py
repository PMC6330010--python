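"""Reading and writing models and results.

Models are read from SBML (via cobrapy), from a self-contained native JSON
schema, or from a long-format TSV of (metabolite, reaction, coefficient)
triplets.  Topes are written as TSV of "-"/"+" symbols (one column per
reaction), EFMs as TSV of integer-normalized fluxes, and run reports as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .efm import EFM, EFMSet
from .enumerate_topes import EnumerationResult, FluxTope
from .model import MetabolicNetwork, ModelError
from .signs import FullSignVector, SignVector


class ParseError(ModelError):
    """Input file does not parse in the requested dialect."""


#: TSV rows whose metabolite column equals this marker carry reversibility
#: flags instead of stoichiometry (coefficient 1 = reversible).
REV_MARKER = "!reversible"


def read_model(path: str | Path, format: str | None = None
               ) -> MetabolicNetwork:
    """Read a metabolic model from SBML, native JSON or triplet TSV.

    The format is inferred from the suffix when not given.  Only internal
    metabolites enter the stoichiometric matrix; SBML species flagged
    ``boundaryCondition`` are dropped.  Reaction order is preserved.
    """
    path = Path(path)
    if format is None:
        format = {".xml": "sbml", ".sbml": "sbml", ".json": "json",
                  ".tsv": "tsv"}.get(path.suffix.lower())
    if format == "json":
        return _read_json(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ParseError(f"unknown model format {format!r} for {path}")


def _read_json(path: Path) -> MetabolicNetwork:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    try:
        mets = list(doc["metabolites"])
        reactions = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing key {exc}") from exc
    if not reactions:
        raise ParseError(f"{path}: empty reaction list")
    met_index = {m: i for i, m in enumerate(mets)}
    r = len(reactions)
    N = np.zeros((len(mets), r))
    ids, rev, lb, ub, obj = [], [], [], [], []
    has_bounds = has_obj = False
    for j, rec in enumerate(reactions):
        rid = rec.get("id")
        if rid is None:
            raise ParseError(f"{path}: reaction #{j} lacks an id")
        if rid in ids:
            raise ParseError(f"{path}: duplicate reaction id {rid!r}")
        ids.append(rid)
        for met, coef in rec.get("stoich", {}).items():
            if met not in met_index:
                raise ParseError(
                    f"{path}: reaction {rid!r} references unknown "
                    f"metabolite {met!r}")
            N[met_index[met], j] = float(coef)
        rev.append(bool(rec.get("reversible", False)))
        lo, hi = rec.get("lb"), rec.get("ub")
        has_bounds = has_bounds or lo is not None or hi is not None
        lb.append(-np.inf if lo is None else float(lo))
        ub.append(np.inf if hi is None else float(hi))
        c = rec.get("obj", 0.0)
        has_obj = has_obj or bool(c)
        obj.append(float(c))
    lbv = np.array(lb) if has_bounds else None
    if lbv is not None:
        lbv[~np.array(rev)] = np.maximum(lbv[~np.array(rev)], 0.0)
    return MetabolicNetwork(
        N=N, metabolite_ids=tuple(mets), reaction_ids=tuple(ids),
        reversible=np.array(rev),
        lb=lbv, ub=np.array(ub) if has_bounds else None,
        objective=np.array(obj) if has_obj else None)


def _read_tsv(path: Path) -> MetabolicNetwork:
    triplets, rev_flags = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}")
            met, rxn, coef = parts
            try:
                val = float(coef)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: bad coefficient {coef!r}") from exc
            if met == REV_MARKER:
                rev_flags[rxn] = bool(val)
            else:
                triplets.append((met, rxn, val))
    if not triplets:
        raise ParseError(f"{path}: no stoichiometry rows")
    mets, rxns = [], []
    for met, rxn, _ in triplets:
        if met not in mets:
            mets.append(met)
        if rxn not in rxns:
            rxns.append(rxn)
    for rxn in rev_flags:
        if rxn not in rxns:
            rxns.append(rxn)
    N = np.zeros((len(mets), len(rxns)))
    for met, rxn, val in triplets:
        N[mets.index(met), rxns.index(rxn)] = val
    rev = np.array([rev_flags.get(rxn, False) for rxn in rxns])
    return MetabolicNetwork(N=N, metabolite_ids=tuple(mets),
                            reaction_ids=tuple(rxns), reversible=rev)


def _read_sbml(path: Path) -> MetabolicNetwork:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ParseError(
            "SBML support requires cobrapy (pip install cobra)") from exc
    model = cobra.io.read_sbml_model(str(path))
    mets = [m.id for m in model.metabolites if not m.boundary_condition] \
        if hasattr(model.metabolites[0], "boundary_condition") \
        else [m.id for m in model.metabolites]
    met_index = {m: i for i, m in enumerate(mets)}
    r = len(model.reactions)
    N = np.zeros((len(mets), r))
    ids, rev, lb, ub, obj = [], [], [], [], []
    for j, rxn in enumerate(model.reactions):
        ids.append(rxn.id)
        for met, coef in rxn.metabolites.items():
            if met.id in met_index:
                N[met_index[met.id], j] = coef
        rev.append(rxn.lower_bound < 0)
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        obj.append(rxn.objective_coefficient)
    return MetabolicNetwork(
        N=N, metabolite_ids=tuple(mets), reaction_ids=tuple(ids),
        reversible=np.array(rev), lb=np.array(lb, float),
        ub=np.array(ub, float),
        objective=np.array(obj, float) if any(obj) else None)


def write_model(network: MetabolicNetwork, path: str | Path,
                format: str = "json") -> None:
    """Write a model in the native JSON schema or as triplet TSV."""
    path = Path(path)
    if format == "json":
        doc = {
            "metabolites": list(network.metabolite_ids),
            "reactions": [
                {
                    "id": rid,
                    "stoich": {
                        network.metabolite_ids[i]: network.N[i, j]
                        for i in range(network.m) if network.N[i, j] != 0
                    },
                    "reversible": bool(network.reversible[j]),
                    **({"lb": _num(network.lb[j])}
                       if network.lb is not None
                       and np.isfinite(network.lb[j]) else {}),
                    **({"ub": _num(network.ub[j])}
                       if network.ub is not None
                       and np.isfinite(network.ub[j]) else {}),
                    **({"obj": _num(network.objective[j])}
                       if network.objective is not None
                       and network.objective[j] else {}),
                }
                for j, rid in enumerate(network.reaction_ids)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    elif format == "tsv":
        with open(path, "w") as fh:
            for j, rid in enumerate(network.reaction_ids):
                for i in range(network.m):
                    if network.N[i, j] != 0:
                        fh.write(f"{network.metabolite_ids[i]}\t{rid}\t"
                                 f"{_num(network.N[i, j])}\n")
                if network.reversible[j]:
                    fh.write(f"{REV_MARKER}\t{rid}\t1\n")
    else:
        raise ParseError(f"cannot write format {format!r}")


def _num(x):
    xf = float(x)
    return int(xf) if xf == int(xf) else xf


def write_topes(topes: list[FluxTope] | EnumerationResult,
                path: str | Path, reaction_ids=None) -> None:
    """Write topes as TSV of "-"/"+" symbols, one column per reaction."""
    if isinstance(topes, EnumerationResult):
        reaction_ids = topes.reaction_ids
        topes = topes.topes
    if not reaction_ids:
        raise ValueError("reaction ids required for the header")
    with open(path, "w") as fh:
        fh.write("\t".join(reaction_ids) + "\n")
        for t in topes:
            fh.write("\t".join(str(t.tau)[k]
                               for k in range(len(reaction_ids))) + "\n")


def read_topes(path: str | Path) -> tuple[list[str], list[SignVector]]:
    """Read a tope TSV back into (reaction ids, sign vectors)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty tope file")
    header = lines[0].split("\t")
    vectors = []
    for lineno, line in enumerate(lines[1:], 2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(f"{path}:{lineno}: wrong column count")
        vectors.append(SignVector("".join(cells)))
    return header, vectors


def write_efms(efms: EFMSet, path: str | Path, reaction_ids) -> None:
    """Write EFMs as TSV of integer-normalized fluxes."""
    with open(path, "w") as fh:
        fh.write("\t".join(reaction_ids) + "\n")
        for e in sorted(efms, key=lambda e: e.flux):
            fh.write("\t".join(str(x) for x in e.flux) + "\n")


def read_efms(path: str | Path) -> tuple[list[str], EFMSet]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    efms = [EFM(flux=tuple(int(x) for x in ln.split("\t")))
            for ln in lines[1:]]
    return header, EFMSet(efms=efms, tope="global")


def write_report(report: dict, path: str | Path) -> None:
    """Write a run report as JSON (numpy scalars coerced)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=default)
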