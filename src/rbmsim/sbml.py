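"""Minimal SBML importer for irreversible mass-action models.

Supports the subset needed to translate SBML (Level 2 or 3) models into
reaction-based form: every reaction must follow mass-action kinetics
with a single rate constant, i.e. its kinetic law must be

    k * [reactant_1]^a_1 * ... * [reactant_n]^a_n

with the exponents equal to the listed reactant stoichiometries.
Reversible reactions are accepted when their law is the difference of
two such monomials (kf * reactants - kr * products) and are split into
a forward and a backward irreversible reaction.  Anything else (e.g. a
Michaelis-Menten rate) raises :class:`UnsupportedModelError` naming the
offending reaction.

Compartment symbols appearing as plain multiplicative factors are
treated as part of the rate constant only when their size is 1 (the
usual convention in models written per-volume); other sizes are
rejected to avoid silent unit errors.

The MathML kinetic law is converted to a sympy expression and compared
symbolically against the expected mass-action monomial, so equivalent
algebraic spellings (nested times, power written as repeated product,
...) are all recognized.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from typing import Optional

import numpy as np
import sympy as sp

from .model import RBM

__all__ = ["import_sbml", "UnsupportedModelError"]


class UnsupportedModelError(RuntimeError):
    pass


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_all(node, name: str):
    return [el for el in node.iter() if _local(el.tag) == name]


def _children(node, name: str):
    return [el for el in node if _local(el.tag) == name]


def _mathml_to_sympy(node, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    tag = _local(node.tag)
    if tag == "math":
        kids = list(node)
        if len(kids) != 1:
            raise UnsupportedModelError("malformed MathML (expected one root)")
        return _mathml_to_sympy(kids[0], symbols)
    if tag == "ci":
        name = (node.text or "").strip()
        return symbols.setdefault(name, sp.Symbol(name, positive=True))
    if tag == "cn":
        ctype = node.attrib.get("type", "real")
        if ctype == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            mant, expo = float(parts[0]), float(parts[1])
            return sp.Float(mant * 10**expo)
        return sp.Float(float((node.text or "0").strip()))
    if tag == "apply":
        kids = list(node)
        op = _local(kids[0].tag)
        args = [_mathml_to_sympy(k, symbols) for k in kids[1:]]
        if op == "times":
            out = sp.Integer(1)
            for a in args:
                out = out * a
            return out
        if op == "plus":
            return sp.Add(*args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        raise UnsupportedModelError(f"unsupported MathML operator: {op}")
    raise UnsupportedModelError(f"unsupported MathML element: {tag}")


def _monomial(species: dict[str, sp.Symbol], stoich: dict[str, float]) -> sp.Expr:
    out = sp.Integer(1)
    for sid, a in stoich.items():
        out = out * species[sid] ** int(a)
    return out


def import_sbml(path: os.PathLike | str) -> RBM:
    """Translate a mass-action SBML file into an :class:`~rbmsim.model.RBM`."""
    tree = ET.parse(path)
    root = tree.getroot()
    model = _find_all(root, "model")
    if not model:
        raise UnsupportedModelError("no <model> element found")
    model = model[0]

    comp_size: dict[str, float] = {}
    for comp in _find_all(model, "compartment"):
        comp_size[comp.attrib.get("id", "")] = float(comp.attrib.get("size", 1.0))

    species_ids: list[str] = []
    x0: list[float] = []
    for spe in _find_all(model, "species"):
        sid = spe.attrib["id"]
        species_ids.append(sid)
        if "initialConcentration" in spe.attrib:
            x0.append(float(spe.attrib["initialConcentration"]))
        elif "initialAmount" in spe.attrib:
            x0.append(float(spe.attrib["initialAmount"]))
        else:
            x0.append(0.0)
    index = {sid: j for j, sid in enumerate(species_ids)}
    syms = {sid: sp.Symbol(sid, positive=True) for sid in species_ids}

    global_params: dict[str, float] = {}
    for lst in _children(model, "listOfParameters"):
        for par in _find_all(lst, "parameter"):
            if "value" in par.attrib:
                global_params[par.attrib["id"]] = float(par.attrib["value"])

    rows_a: list[np.ndarray] = []
    rows_b: list[np.ndarray] = []
    ks: list[float] = []

    for rxn in _find_all(model, "reaction"):
        rid = rxn.attrib.get("id", "?")
        reversible = rxn.attrib.get("reversible", "false").lower() == "true"
        reactants: dict[str, float] = {}
        products: dict[str, float] = {}
        for side, store in (("listOfReactants", reactants), ("listOfProducts", products)):
            for lst in _children(rxn, side):
                for ref in _find_all(lst, "speciesReference"):
                    sid = ref.attrib["species"]
                    st = float(ref.attrib.get("stoichiometry", 1.0))
                    if st != int(st) or st < 0:
                        raise UnsupportedModelError(
                            f"reaction {rid}: non-integer stoichiometry {st}"
                        )
                    store[sid] = store.get(sid, 0.0) + st

        laws = _children(rxn, "kineticLaw")
        if not laws:
            raise UnsupportedModelError(f"reaction {rid}: no kinetic law")
        law = laws[0]
        local_params: dict[str, float] = {}
        for lst in law:
            if _local(lst.tag) in ("listOfParameters", "listOfLocalParameters"):
                for par in lst:
                    if "value" in par.attrib:
                        local_params[par.attrib["id"]] = float(par.attrib["value"])
        params = {**global_params, **local_params}

        math = [el for el in law if _local(el.tag) == "math"]
        if not math:
            raise UnsupportedModelError(f"reaction {rid}: kinetic law has no math")
        symbols = dict(syms)
        expr = _mathml_to_sympy(math[0], symbols)
        # substitute unit-sized compartments and numeric parameters
        subs: dict[sp.Symbol, sp.Expr] = {}
        for name, sym in symbols.items():
            if name in comp_size:
                if comp_size[name] != 1.0:
                    raise UnsupportedModelError(
                        f"reaction {rid}: compartment {name} has size != 1"
                    )
                subs[sym] = sp.Integer(1)
        expr = expr.subs(subs)

        param_syms = {
            name: sym
            for name, sym in symbols.items()
            if name in params and name not in index
        }

        def _match(stoich: dict[str, float]) -> Optional[float]:
            """Return k if expr == k * monomial(stoich), else None."""
            mono = _monomial(syms, stoich)
            ratio = sp.simplify(expr / mono)
            free = ratio.free_symbols & set(syms[s] for s in species_ids)
            if free:
                return None
            val = ratio.subs({sym: params[name] for name, sym in param_syms.items()})
            try:
                val = float(val)
            except TypeError:
                return None
            return val if val > 0 else None

        if not reversible:
            k = _match(reactants)
            if k is None:
                raise UnsupportedModelError(
                    f"reaction {rid}: kinetic law is not irreversible mass-action"
                )
            fwd = [(reactants, products, k)]
        else:
            # expect kf * reactants - kr * products
            fwd = None
            expanded = sp.expand(expr)
            terms = sp.Add.make_args(expanded)
            if len(terms) == 2:
                mono_f = _monomial(syms, reactants)
                mono_r = _monomial(syms, products)
                kf = kr = None
                for term in terms:
                    rf = sp.simplify(term / mono_f)
                    rr = sp.simplify(-term / mono_r)
                    spc = set(syms[s] for s in species_ids)
                    if not (rf.free_symbols & spc):
                        kf = float(rf.subs({s: params[n] for n, s in param_syms.items()}))
                    elif not (rr.free_symbols & spc):
                        kr = float(rr.subs({s: params[n] for n, s in param_syms.items()}))
                if kf is not None and kr is not None and kf > 0 and kr > 0:
                    fwd = [(reactants, products, kf), (products, reactants, kr)]
            if fwd is None:
                raise UnsupportedModelError(
                    f"reaction {rid}: reversible law is not mass-action"
                )

        for rea, pro, k in fwd:
            ra = np.zeros(len(species_ids))
            rb = np.zeros(len(species_ids))
            for sid, st in rea.items():
                ra[index[sid]] = st
            for sid, st in pro.items():
                rb[index[sid]] = st
            rows_a.append(ra)
            rows_b.append(rb)
            ks.append(k)

    if not rows_a:
        raise UnsupportedModelError("model contains no reactions")
    return RBM(
        species_names=species_ids,
        A=np.vstack(rows_a),
        B=np.vstack(rows_b),
        K=np.array(ks),
        X0=np.array(x0),
        metadata={"source": str(path), "format": "sbml"},
    )
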