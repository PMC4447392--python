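"""Expansion of the rule-based model into a concrete reaction network.

Species are canonical molecule graphs (tuples of molecules with numbered
bonds).  :func:`enumerate_network` performs a breadth-first reachability
expansion from the initial state: every concrete species reachable by rule
application is listed exactly once, and every concrete instantiation of
every rule becomes one reaction.  A rule whose DNA pattern leaves the
``id`` component unconstrained instantiates once per DNA site, so a single
repair rule codes for ``n_dna_sites`` reaction families.

The module also provides :func:`simulate_network`, a plain Gillespie
direct-method simulator over the expanded network.  It is intentionally
simple and slow; its role is to serve as an independent reference for the
optimized network-free engine on small submodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    CompConstraint,
    ModelSpec,
    ModelValidationError,
    MolPattern,
    RateFunction,
    RuleSpec,
    _parse_mol_pattern,
)

__all__ = ["Species", "Reaction", "ReactionNetwork", "enumerate_network",
           "simulate_network", "NetworkError"]


class NetworkError(RuntimeError):
    pass


# A molecule instance: (name, ((comp, state|None, bond_id|None), ...))
Mol = tuple
# A species (connected complex): tuple of Mol, canonically ordered.
Species = tuple


def _canonical(mols: list[list]) -> Species:
    """Canonicalize a connected complex.

    Molecules are sorted by (name, component states); bond ids are
    renumbered in order of first appearance.  The model never forms a
    complex with two molecules of the same name, which makes the sort a
    full canonical order (asserted).
    """
    keyed = sorted(
        mols, key=lambda m: (m[0], tuple((c[0], c[1]) for c in m[1]))
    )
    names = [m[0] for m in keyed]
    if len(set(names)) != len(names):  # pragma: no cover - guarded by model design
        raise NetworkError("complex with duplicate molecule names is not supported")
    bond_map: dict[int, int] = {}
    out = []
    for name, comps in keyed:
        new_comps = []
        for cname, state, bond in comps:
            if bond is not None:
                bond = bond_map.setdefault(bond, len(bond_map))
            new_comps.append((cname, state, bond))
        out.append((name, tuple(new_comps)))
    return tuple(out)


def species_from_pattern(pat: MolPattern) -> Species:
    """Turn a fully specified single-molecule pattern into a species."""
    comps = []
    for cname, cons in pat.comps:
        state = None
        if cons.states is not None:
            if len(cons.states) != 1:
                raise ModelValidationError(
                    f"initial species {pat.molecule}.{cname} not concrete"
                )
            state = cons.states[0]
        if cons.bond not in ("any", "unbound"):
            raise ModelValidationError("initial species must be unbound")
        comps.append((cname, state, None))
    return _canonical([[pat.molecule, tuple(comps)]])


def _mol_index(species: Species, name: str) -> int | None:
    for i, m in enumerate(species):
        if m[0] == name:
            return i
    return None


def _comp(species: Species, mi: int, cname: str):
    for c in species[mi][1]:
        if c[0] == cname:
            return c
    raise NetworkError(f"{species[mi][0]} has no component {cname}")


def _match_complex(patterns: Sequence[MolPattern], species: Species) -> bool:
    """Check whether a pattern complex embeds in a species complex.

    Molecule names are unique per complex, so the embedding (if any) is
    unique and determined by name.
    """
    # map pattern molecule -> species molecule index
    mapping: dict[str, int] = {}
    for pat in patterns:
        mi = _mol_index(species, pat.molecule)
        if mi is None:
            return False
        mapping[pat.molecule] = mi
    # bond labels: label -> list of (mol index, comp name)
    labels: dict[int, list[tuple[int, str]]] = {}
    for pat in patterns:
        mi = mapping[pat.molecule]
        for cname, cons in pat.comps:
            _, state, bond = _comp(species, mi, cname)
            if cons.states is not None and state not in cons.states:
                return False
            if cons.bond == "bound" and bond is None:
                return False
            if cons.bond == "unbound" and bond is not None:
                return False
            if isinstance(cons.bond, int):
                if bond is None:
                    return False
                labels.setdefault(cons.bond, []).append((mi, cname))
    for ends in labels.values():
        (mi_a, ca), (mi_b, cb) = ends
        bond_a = _comp(species, mi_a, ca)[2]
        bond_b = _comp(species, mi_b, cb)[2]
        if bond_a != bond_b:
            return False
    return True


def _apply_rule(
    rule: RuleSpec, reactants: Sequence[Species], model: ModelSpec
) -> tuple[Species, ...]:
    """Apply a matched rule to concrete reactant species; return products."""
    # Build a mutable union graph.  Molecule identity across the rule is by
    # name (validated unique per side).
    mols: list[list] = []  # [name, {comp: [state, bond_key]}]
    bond_offset = 0
    name_to_idx: dict[str, int] = {}
    for sp in reactants:
        local_bonds = {}
        for name, comps in sp:
            entry = [name, {c[0]: [c[1], None] for c in comps}]
            for cname, state, bond in comps:
                if bond is not None:
                    entry[1][cname][1] = ("r", bond_offset, bond)
            mols.append(entry)
            name_to_idx[name] = len(mols) - 1
        bond_offset += 1

    reactant_names = {p.molecule for cx in rule.reactants for p in cx}
    product_names = {p.molecule for cx in rule.products for p in cx}

    # molecules created by the rule
    new_bond_labels: dict[int, list[tuple[int, str]]] = {}
    for cx in rule.products:
        for pat in cx:
            if pat.molecule in reactant_names:
                continue
            mspec = model.molecule(pat.molecule)
            entry = [pat.molecule, {}]
            for cspec in mspec.components:
                cons = pat.constraint(cspec.name)
                if cspec.states:
                    if cons is None or cons.states is None or len(cons.states) != 1:
                        raise ModelValidationError(
                            f"rule {rule.name}: created molecule "
                            f"{pat.molecule}.{cspec.name} must have a concrete state"
                        )
                    entry[1][cspec.name] = [cons.states[0], None]
                else:
                    entry[1][cspec.name] = [None, None]
            mols.append(entry)
            name_to_idx[pat.molecule] = len(mols) - 1

    # apply product-side constraints
    for cx in rule.products:
        for pat in cx:
            idx = name_to_idx[pat.molecule]
            for cname, cons in pat.comps:
                slot = mols[idx][1][cname]
                if cons.states is not None and len(cons.states) == 1:
                    slot[0] = cons.states[0]
                if cons.bond == "unbound":
                    if slot[1] is not None:
                        # break the bond from both ends
                        key = slot[1]
                        for other in mols:
                            for oslot in other[1].values():
                                if oslot[1] == key:
                                    oslot[1] = None
                        slot[1] = None
                elif isinstance(cons.bond, int):
                    new_bond_labels.setdefault(cons.bond, []).append((idx, cname))

    for label, ends in new_bond_labels.items():
        if len(ends) != 2:
            raise ModelValidationError(
                f"rule {rule.name}: product bond {label} has {len(ends)} ends"
            )
        key = ("n", label)
        (ia, ca), (ib, cb) = ends
        mols[ia][1][ca][1] = key
        mols[ib][1][cb][1] = key

    # deleted molecules
    deleted = set()
    for name in reactant_names - product_names:
        idx = name_to_idx[name]
        for slot in mols[idx][1].values():
            if slot[1] is not None:
                raise NetworkError(
                    f"rule {rule.name}: cannot delete bound molecule {name}"
                )
        deleted.add(idx)

    # split into connected components
    alive = [i for i in range(len(mols)) if i not in deleted]
    parent = {i: i for i in alive}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    bond_ends: dict[object, list[tuple[int, str]]] = {}
    for i in alive:
        for cname, slot in mols[i][1].items():
            if slot[1] is not None:
                bond_ends.setdefault(slot[1], []).append((i, cname))
    for ends in bond_ends.values():
        if len(ends) != 2:
            raise NetworkError(f"rule {rule.name}: dangling bond after transform")
        a, b = find(ends[0][0]), find(ends[1][0])
        parent[a] = b

    groups: dict[int, list[int]] = {}
    for i in alive:
        groups.setdefault(find(i), []).append(i)

    products = []
    for members in groups.values():
        # renumber bonds within the component
        local: dict[object, int] = {}
        comp_mols = []
        for i in members:
            name = mols[i][0]
            comps = []
            for cname, slot in mols[i][1].items():
                bond = None
                if slot[1] is not None:
                    bond = local.setdefault(slot[1], len(local))
                comps.append((cname, slot[0], bond))
            comp_mols.append([name, tuple(comps)])
        products.append(_canonical(comp_mols))
    return tuple(products)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    rule: str
    reactants: tuple[int, ...]  # species indices
    products: tuple[int, ...]
    rate: str


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    rule_counts: dict[str, int]
    model: ModelSpec

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self) -> dict[Species, int]:
        return {s: i for i, s in enumerate(self.species)}


def initial_species(model: ModelSpec) -> dict[Species, float]:
    """Seed species and their initial counts for the model's preset."""
    seeds: dict[Species, float] = {}
    for pat_str, ref in model.initial_pools.items():
        sp = species_from_pattern(_parse_mol_pattern(pat_str))
        seeds[sp] = model.parameters.value(ref)
    dna = model.molecule("DNA")
    for sid in dna.component("id").states:
        sp = _canonical(
            [["DNA", (("id", sid, None), ("site", "ok", None), ("h2ax", "u", None))]]
        )
        seeds[sp] = 1.0
    return seeds


def enumerate_network(
    model: ModelSpec,
    max_species: int = 100_000,
    seeds: Mapping[Species, float] | None = None,
) -> ReactionNetwork:
    """Expand the rule set into the reachable concrete reaction network.

    ``seeds`` overrides the initial species set (defaults to the model's
    initial state); reachability is computed from it.  Raises
    :class:`NetworkError` with the partial counts if the expansion exceeds
    ``max_species`` (non-terminating rule sets).
    """
    model.validate()
    if seeds is None:
        seeds = initial_species(model)
    species: list[Species] = []
    index: dict[Species, int] = {}
    reactions: list[Reaction] = []
    seen_rxn: set = set()
    rule_counts: dict[str, int] = {r.name: 0 for r in model.rules}

    # per (rule, reactant position) match lists
    rules = list(model.rules)
    matches: list[list[list[int]]] = [
        [[] for _ in rule.reactants] for rule in rules
    ]

    def add_species(sp: Species) -> int:
        if sp in index:
            return index[sp]
        if len(species) >= max_species:
            raise NetworkError(
                f"species bound exceeded: {len(species)} species, "
                f"{len(reactions)} reactions so far"
            )
        index[sp] = len(species)
        species.append(sp)
        worklist.append(sp)
        return index[sp]

    def emit(rule_i: int, combo: tuple[int, ...]) -> None:
        rule = rules[rule_i]
        prods = _apply_rule(rule, [species[i] for i in combo], model)
        prod_ids = tuple(sorted(add_species(p) for p in prods))
        sig = (rule_i, tuple(sorted(combo)), prod_ids)
        if sig in seen_rxn:
            return
        seen_rxn.add(sig)
        reactions.append(
            Reaction(rule.name, tuple(combo), prod_ids, rule.rate)
        )
        rule_counts[rule.name] += 1

    worklist: list[Species] = []
    for sp in seeds:
        add_species(sp)

    # synthesis rules (no reactants) fire unconditionally
    for ri, rule in enumerate(rules):
        if not rule.reactants:
            emit(ri, ())

    while worklist:
        sp = worklist.pop()
        si = index[sp]
        for ri, rule in enumerate(rules):
            for pi, pat_cx in enumerate(rule.reactants):
                if not _match_complex(pat_cx, sp):
                    continue
                matches[ri][pi].append(si)
                # build combos with this species at position pi
                other_lists = [
                    matches[ri][qi] if qi != pi else [si]
                    for qi in range(len(rule.reactants))
                ]
                # avoid double-counting combos where another position already
                # includes this species from an earlier registration
                def rec(qi: int, combo: list[int]):
                    if qi == len(other_lists):
                        emit(ri, tuple(combo))
                        return
                    for cand in other_lists[qi]:
                        # skip combos counted when cand was registered later
                        rec(qi + 1, combo + [cand])

                rec(0, [])
    return ReactionNetwork(species, reactions, rule_counts, model)


# ---------------------------------------------------------------------------
# reference Gillespie simulation on the expanded network (oracle use only)
# ---------------------------------------------------------------------------


def _observable_matrix(model: ModelSpec, network: ReactionNetwork) -> tuple[list[str], np.ndarray]:
    names = list(model.observables)
    mat = np.zeros((len(names), len(network.species)))
    for r, name in enumerate(names):
        pat = _parse_mol_pattern(model.observables[name])
        for i, sp in enumerate(network.species):
            if _match_complex((pat,), sp):
                mat[r, i] = 1.0
    return names, mat


def _function_value(f: RateFunction, model: ModelSpec, obs: Mapping[str, float]) -> float:
    p = model.parameters
    if f.gate_obs is not None:
        if not _cmp(obs[f.gate_obs], f.gate_op, p.value(f.gate_threshold)):
            return 0.0
    if f.kind == "linear":
        return p.value(f.value_true) * obs[f.obs]
    cond = _cmp(obs[f.obs], f.op, p.value(f.threshold))
    return p.value(f.value_true) if cond else p.value(f.value_false)


def _cmp(x: float, op: str, t: float) -> bool:
    return {
        "gt": x > t, "ge": x >= t, "lt": x < t, "le": x <= t, "eq": x == t
    }[op]


def simulate_network(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    sample_every: float = 5.0,
    init_counts: Mapping[Species, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-method SSA over the expanded network.

    Returns ``(times, counts)`` with ``counts[t_i, species_i]``.  Only
    suitable for small networks; used as an independent check of the
    network-free engine.
    """
    model = network.model
    idx = network.species_index()
    counts = np.zeros(len(network.species))
    seeds = init_counts if init_counts is not None else initial_species(model)
    for sp, c in seeds.items():
        counts[idx[sp]] = c
    rng = np.random.default_rng(seed)

    grid = np.arange(0.0, t_end + 1e-9, sample_every)
    out = np.zeros((len(grid), len(counts)))
    gi = 0
    t = 0.0

    fn_by_name = {f.name: f for f in model.functions}
    obs_names, obs_mat = _observable_matrix(model, network)
    n_rxn = len(network.reactions)
    const_k = np.array(
        [
            model.parameters.value(r.rate) if r.rate not in fn_by_name else 0.0
            for r in network.reactions
        ]
    )
    fn_rxns = [
        (i, fn_by_name[r.rate]) for i, r in enumerate(network.reactions)
        if r.rate in fn_by_name
    ]
    # reactant index arrays (at most two reactants in this rule dialect)
    r1 = np.full(n_rxn, -1, dtype=np.int64)
    r2 = np.full(n_rxn, -1, dtype=np.int64)
    for i, rxn in enumerate(network.reactions):
        if len(rxn.reactants) > 2:  # pragma: no cover - dialect guard
            raise NetworkError("more than two reactants not supported")
        if len(rxn.reactants) >= 1:
            r1[i] = rxn.reactants[0]
        if len(rxn.reactants) == 2:
            r2[i] = rxn.reactants[1]
    k_vec = const_k.copy()
    while True:
        obs = dict(zip(obs_names, obs_mat @ counts))
        for i, fn in fn_rxns:
            k_vec[i] = _function_value(fn, model, obs)
        props = k_vec.copy()
        mask1 = r1 >= 0
        props[mask1] *= counts[r1[mask1]]
        mask2 = r2 >= 0
        props[mask2] *= counts[r2[mask2]]
        total = props.sum()
        if total <= 0:
            while gi < len(grid):
                out[gi] = counts
                gi += 1
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        while gi < len(grid) and grid[gi] < t_next:
            out[gi] = counts
            gi += 1
        if gi >= len(grid):
            break
        t = t_next
        ri = np.searchsorted(np.cumsum(props), rng.random() * total)
        rxn = network.reactions[ri]
        for si in rxn.reactants:
            counts[si] -= 1
        for si in rxn.products:
            counts[si] += 1
        if (counts < 0).any():
            raise NetworkError("negative count: inconsistent network")
    return grid, out
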