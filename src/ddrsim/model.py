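"""Declarative core of the integrated DSB-repair / p53-senescence model.

The model couples three layers in a single cell:

* **Damage & repair** — 50 independent DNA sites that acquire simple or
  complex double-strand breaks (sdsb/cdsb) from reactive oxygen species
  (ROS) or irradiation, and are repaired by the fast DNA-PKcs-dependent
  pathway (Ku70/80 -> DNA-PKcs -> ligase IV) or the slower backup pathway
  (PARP-1 -> ligase III).  Ku carries a redox-sensitive cysteine: oxidation
  accelerates its dissociation from breaks.
* **Focus formation** — broken sites recruit active ATM to phosphorylated
  H2AX and mature into a damage focus; ligation of a break requires a
  formed focus, but foci form and resolve independently of repair.
* **Signalling** — a pool of ATM activated by damage phosphorylates p53 and
  MDM2; the p53–MDM2 negative feedback produces p53 pulses; p53 drives p21
  (the molecule ``P``), which advances an integer senescence counter
  (``Sen``) and, through GADD45, feeds back on ROS production.  When the
  counter reaches 10 the cell switches irreversibly to early senescence and
  Ku/PARP are depleted toward senescent levels.

Everything is declared in a small rule dialect and expanded/validated by
:mod:`ddrsim.network`.  The stochastic engine (:mod:`ddrsim.engine`)
executes the same rule set network-free.

Rule dialect
------------
A rule is one line::

    name: A(c~s!1) . B(d!1) + C(e~x) -> A(c~s!-) + B(d!-) + C(e~y) @ rate [tag]

``.`` joins molecules inside one connected complex, ``+`` separates
complexes, ``0`` denotes an empty side.  Component annotations:

``~s1~s2``  state must be one of the listed states (a single state on the
            product side *sets* the state);
``!n``      bond labelled ``n`` (shared by exactly two components);
``!+``      bound to anything;  ``!-``  unbound;
no ``!``    the bond is irrelevant (note: BioNetGen proper would read an
            unannotated component as *unbound*; this dialect deviates so
            rules need not be duplicated).

``@ rate`` names a rate constant or a rate function; ``[tag]`` is one of
repair/focus/signalling/senescence/damage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MoleculeSpec",
    "ComponentSpec",
    "CompConstraint",
    "MolPattern",
    "RuleSpec",
    "RateFunction",
    "ParamEntry",
    "ParameterSet",
    "ModelSpec",
    "ModelValidationError",
    "build_default_model",
    "parse_rule",
    "parse_pattern",
    "load_model",
    "save_model",
    "PRESETS",
]

PRESETS = ("MRC5", "MCF7", "high_p53")

N_DNA_SITES_DEFAULT = 50


class ModelValidationError(ValueError):
    """Raised when a model specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# molecule declarations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSpec:
    """One component of a molecule: optional state list, optional bond site."""

    name: str
    states: tuple[str, ...] = ()
    binds: bool = False


@dataclass(frozen=True)
class MoleculeSpec:
    name: str
    components: tuple[ComponentSpec, ...] = ()

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ModelValidationError(
                f"duplicate component names in molecule {self.name}"
            )

    def component(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"{self.name} has no component {name!r}")


# ---------------------------------------------------------------------------
# patterns and rules
# ---------------------------------------------------------------------------

#: bond constraint values: "any", "bound", "unbound", or an int label
Bond = object


@dataclass(frozen=True)
class CompConstraint:
    states: tuple[str, ...] | None = None  # None = unconstrained
    bond: object = "any"  # "any" | "bound" | "unbound" | int


@dataclass(frozen=True)
class MolPattern:
    molecule: str
    comps: tuple[tuple[str, CompConstraint], ...] = ()

    def constraint(self, comp: str) -> CompConstraint | None:
        for name, c in self.comps:
            if name == comp:
                return c
        return None


@dataclass(frozen=True)
class RuleSpec:
    """A reaction rule: reactant pattern complexes -> product pattern complexes.

    ``reactants``/``products`` are tuples of pattern complexes; a pattern
    complex is a tuple of :class:`MolPattern` joined by shared bond labels.
    Molecule names must be unique across each side; product molecules are
    matched to reactant molecules by name.
    """

    name: str
    reactants: tuple[tuple[MolPattern, ...], ...]
    products: tuple[tuple[MolPattern, ...], ...]
    rate: str
    tag: str
    text: str = ""

    TAGS = ("repair", "focus", "signalling", "senescence", "damage")

    def __post_init__(self) -> None:
        if self.tag not in self.TAGS:
            raise ModelValidationError(f"rule {self.name}: unknown tag {self.tag!r}")
        for side in (self.reactants, self.products):
            names = [m.molecule for cx in side for m in cx]
            if len(names) != len(set(names)):
                raise ModelValidationError(
                    f"rule {self.name}: molecule names must be unique per side"
                )


@dataclass(frozen=True)
class RateFunction:
    """Conditional or observable-scaled propensity contribution.

    kinds:

    * ``threshold`` — value_true if ``obs <op> threshold`` else value_false;
    * ``linear``    — ``slope * obs`` (slope given by ``value_true``).

    An optional gate (``gate_obs <gate_op> gate_threshold``) must also hold,
    otherwise the rate is 0.  All numeric fields are *parameter names*
    resolved against the model's :class:`ParameterSet` (or numeric
    literals).
    """

    name: str
    kind: str  # "threshold" | "linear"
    obs: str
    op: str = "gt"  # "gt" | "le" | "ge" | "lt" | "eq"
    threshold: str | float = 0.0
    value_true: str | float = 0.0
    value_false: str | float = 0.0
    gate_obs: str | None = None
    gate_op: str = "eq"
    gate_threshold: str | float = 1.0

    OPS = {"gt", "ge", "lt", "le", "eq"}

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "linear"):
            raise ModelValidationError(f"function {self.name}: bad kind {self.kind!r}")
        if self.op not in self.OPS or self.gate_op not in self.OPS:
            raise ModelValidationError(f"function {self.name}: bad operator")

    def param_refs(self) -> list[str]:
        refs = []
        for v in (self.threshold, self.value_true, self.value_false, self.gate_threshold):
            if isinstance(v, str):
                refs.append(v)
        return refs


PROVENANCES = ("original-NHEJ", "original-senescence", "merged", "new", "calibrated")


@dataclass(frozen=True)
class ParamEntry:
    value: float
    units: str
    provenance: str = "calibrated"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ModelValidationError("rate constants must be non-negative")
        if self.provenance not in PROVENANCES:
            raise ModelValidationError(f"unknown provenance {self.provenance!r}")
        if not self.units:
            raise ModelValidationError("units string required")


class ParameterSet(dict):
    """Named map rate-constant -> :class:`ParamEntry`."""

    def value(self, ref: str | float) -> float:
        if isinstance(ref, (int, float)):
            return float(ref)
        try:
            return self[ref].value
        except KeyError:
            raise ModelValidationError(f"undefined parameter {ref!r}") from None


# ---------------------------------------------------------------------------
# pattern / rule parsing
# ---------------------------------------------------------------------------

_MOL_RE = re.compile(r"^([A-Za-z_]\w*)\((.*)\)$")
_RULE_RE = re.compile(
    r"^\s*([\w]+)\s*:\s*(.*?)\s*->\s*(.*?)\s*@\s*([\w.]+)\s*\[(\w+)\]\s*$"
)


def _parse_comp(token: str) -> tuple[str, CompConstraint]:
    """Parse e.g. ``site!?~sdsb~cdsb`` or ``h2ax!1~p`` or ``cys~red``."""
    m = re.match(r"^(\w+)((?:!(?:\+|-|\?|\d+))?)((?:~\w+)*)$", token.strip())
    if not m:
        raise ModelValidationError(f"cannot parse component token {token!r}")
    name, bond_tok, states_tok = m.groups()
    if bond_tok in ("", None):
        bond: object = "any"
    else:
        b = bond_tok[1:]
        if b in ("+", "?"):
            bond = "bound"
        elif b == "-":
            bond = "unbound"
        else:
            bond = int(b)
    states = tuple(s for s in states_tok.split("~") if s) or None
    return name, CompConstraint(states=states, bond=bond)


def _parse_mol_pattern(token: str) -> MolPattern:
    m = _MOL_RE.match(token.strip())
    if not m:
        raise ModelValidationError(f"cannot parse molecule pattern {token!r}")
    name, inner = m.groups()
    comps: list[tuple[str, CompConstraint]] = []
    if inner.strip():
        for part in inner.split(","):
            comps.append(_parse_comp(part))
    return MolPattern(molecule=name, comps=tuple(comps))


def parse_pattern(side: str) -> tuple[tuple[MolPattern, ...], ...]:
    """Parse one rule side into a tuple of pattern complexes."""
    side = side.strip()
    if side == "0":
        return ()
    complexes = []
    for cx in side.split(" + "):
        mols = tuple(_parse_mol_pattern(tok) for tok in cx.split(" . ") if tok.strip())
        if not mols:
            raise ModelValidationError(f"empty complex in pattern {side!r}")
        complexes.append(mols)
    return tuple(complexes)


def parse_rule(line: str) -> RuleSpec:
    m = _RULE_RE.match(line)
    if not m:
        raise ModelValidationError(f"cannot parse rule line: {line!r}")
    name, lhs, rhs, rate, tag = m.groups()
    return RuleSpec(
        name=name,
        reactants=parse_pattern(lhs),
        products=parse_pattern(rhs),
        rate=rate,
        tag=tag,
        text=line.strip(),
    )


# ---------------------------------------------------------------------------
# the model container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A closed, validated model: molecules + rules + functions + parameters."""

    preset: str
    molecules: tuple[MoleculeSpec, ...]
    rules: tuple[RuleSpec, ...]
    functions: tuple[RateFunction, ...]
    parameters: ParameterSet
    observables: Mapping[str, str]
    initial_pools: Mapping[str, str]
    n_dna_sites: int = N_DNA_SITES_DEFAULT

    def molecule(self, name: str) -> MoleculeSpec:
        for mspec in self.molecules:
            if mspec.name == name:
                return mspec
        raise KeyError(name)

    def function(self, name: str) -> RateFunction | None:
        for f in self.functions:
            if f.name == name:
                return f
        return None

    def rule(self, name: str) -> RuleSpec:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_dna_sites < 1:
            raise ModelValidationError("n_dna_sites must be >= 1")
        mol_names = {m.name for m in self.molecules}
        fn_names = {f.name for f in self.functions}
        for rule in self.rules:
            for side in (rule.reactants, rule.products):
                for cx in side:
                    labels: dict[int, int] = {}
                    for pat in cx:
                        if pat.molecule not in mol_names:
                            raise ModelValidationError(
                                f"rule {rule.name}: unknown molecule {pat.molecule}"
                            )
                        mspec = self.molecule(pat.molecule)
                        for comp, cons in pat.comps:
                            cspec = mspec.component(comp)
                            if cons.states is not None:
                                for s in cons.states:
                                    if s not in cspec.states:
                                        raise ModelValidationError(
                                            f"rule {rule.name}: {pat.molecule}.{comp} "
                                            f"has no state {s!r}"
                                        )
                            if isinstance(cons.bond, int):
                                labels[cons.bond] = labels.get(cons.bond, 0) + 1
                    for lab, n in labels.items():
                        if n != 2:
                            raise ModelValidationError(
                                f"rule {rule.name}: bond label {lab} used {n} times"
                            )
            if rule.rate not in fn_names:
                self.parameters.value(rule.rate)  # raises if dangling
        for f in self.functions:
            if f.obs not in self.observables or (
                f.gate_obs is not None and f.gate_obs not in self.observables
            ):
                raise ModelValidationError(f"function {f.name}: unknown observable")
            for ref in f.param_refs():
                self.parameters.value(ref)
        for species, ref in self.initial_pools.items():
            self.parameters.value(ref)
            _parse_mol_pattern(species)

    def with_overrides(self, overlay: Mapping[str, float]) -> "ModelSpec":
        """Return a copy with parameter values replaced (provenance kept)."""
        params = ParameterSet(self.parameters)
        for k, v in overlay.items():
            if k not in params:
                raise ModelValidationError(f"unknown parameter {k!r}")
            params[k] = replace(params[k], value=float(v))
        return replace(self, parameters=params)


# ---------------------------------------------------------------------------
# the default integrated model
# ---------------------------------------------------------------------------


def _molecules(n_sites: int) -> tuple[MoleculeSpec, ...]:
    site_ids = tuple(str(i) for i in range(1, n_sites + 1))
    C = ComponentSpec
    return (
        MoleculeSpec("Source_of_ROS"),
        MoleculeSpec("ROS"),
        MoleculeSpec(
            "DNA",
            (
                C("id", states=site_ids),
                C("site", states=("ok", "sdsb", "cdsb"), binds=True),
                C("h2ax", states=("u", "p", "foci"), binds=True),
            ),
        ),
        MoleculeSpec(
            "Ku",
            (C("dna", binds=True), C("cs", binds=True), C("cys", states=("red", "ox"))),
        ),
        MoleculeSpec(
            "DNAPKcs",
            (C("ku", binds=True), C("liIV", binds=True), C("psite", states=("u", "p"))),
        ),
        MoleculeSpec("LiIV", (C("cs", binds=True),)),
        MoleculeSpec("PARP", (C("dna", binds=True), C("liIII", binds=True))),
        MoleculeSpec("LiIII", (C("parp", binds=True),)),
        MoleculeSpec("ATM", (C("state", states=("0", "1")), C("h2ax", binds=True))),
        MoleculeSpec("P"),
        MoleculeSpec("p53_mRNA"),
        MoleculeSpec("p21_mRNA"),
        MoleculeSpec("MDM2_mRNA"),
        MoleculeSpec("GADD45"),
        MoleculeSpec("p53", (C("psite", states=("u", "p")),)),
        MoleculeSpec("MDM2", (C("psite", states=("u", "p")),)),
        MoleculeSpec("p38", (C("psite", states=("u", "p")),)),
        MoleculeSpec(
            "Sen",
            (
                C("int", states=tuple(str(i) for i in range(1, 11))),
                C("State", states=("norm", "sen")),
            ),
        ),
    )


#: DNA-site rules.  Patterns leaving the DNA ``id`` component unconstrained
#: apply to every site, so each line codes for ``n_dna_sites`` reaction sets.
_SITE_RULES = [
    # damage induction and escalation
    "dmg_sdsb: ROS() + DNA(site!-~ok) -> DNA(site!-~sdsb) @ k_dmg_sdsb [damage]",
    "dmg_cdsb: ROS() + DNA(site!-~ok) -> DNA(site!-~cdsb) @ k_dmg_cdsb [damage]",
    "complexify: ROS() + DNA(site~sdsb) -> DNA(site~cdsb) @ k_complexify [damage]",
    # focus formation around the break
    "h2ax_phos_atm: DNA(site!?~sdsb~cdsb, h2ax!-~u) + ATM(state~1, h2ax!-) -> "
    "DNA(site!?~sdsb~cdsb, h2ax!-~p) + ATM(state~1, h2ax!-) @ k_h2ax_phos_atm [focus]",
    "h2ax_phos_pk: DNA(site!1, h2ax!-~u) . Ku(dna!1, cs!2) . DNAPKcs(ku!2, psite~p) -> "
    "DNA(site!1, h2ax!-~p) . Ku(dna!1, cs!2) . DNAPKcs(ku!2, psite~p) @ k_h2ax_phos_pk [focus]",
    "h2ax_dephos: DNA(h2ax!-~p) -> DNA(h2ax!-~u) @ k_h2ax_dephos [focus]",
    "atm_bind: DNA(site~sdsb~cdsb, h2ax!-~p) + ATM(state~1, h2ax!-) -> "
    "DNA(site~sdsb~cdsb, h2ax!1~p) . ATM(state~1, h2ax!1) @ k_atm_bind [focus]",
    "focus_form: DNA(h2ax!1~p) . ATM(h2ax!1) -> DNA(h2ax!1~foci) . ATM(h2ax!1) @ k_focus_form [focus]",
    "focus_res: DNA(h2ax!1~foci) . ATM(h2ax!1) -> DNA(h2ax!-~p) + ATM(h2ax!-) @ k_focus_res [focus]",
    # D-NHEJ: Ku -> DNA-PKcs -> ligase IV
    "ku_bind_red: DNA(site!-~sdsb~cdsb) + Ku(dna!-, cs!-, cys~red) -> "
    "DNA(site!1~sdsb~cdsb) . Ku(dna!1, cs!-, cys~red) @ f_ku_bind [repair]",
    "ku_bind_ox: DNA(site!-~sdsb~cdsb) + Ku(dna!-, cs!-, cys~ox) -> "
    "DNA(site!1~sdsb~cdsb) . Ku(dna!1, cs!-, cys~ox) @ f_ku_bind [repair]",
    "ku_off_red: DNA(site!1) . Ku(dna!1, cs!-, cys~red) -> "
    "DNA(site!-) + Ku(dna!-, cs!-, cys~red) @ k_ku_off_red [repair]",
    "ku_off_ox: DNA(site!1) . Ku(dna!1, cs!-, cys~ox) -> "
    "DNA(site!-) + Ku(dna!-, cs!-, cys~ox) @ k_ku_off_ox [repair]",
    "ku_ox_site: ROS() + Ku(dna!+, cys~red) -> Ku(dna!+, cys~ox) @ k_ku_ox [repair]",
    "ku_red_site: Ku(dna!+, cys~ox) -> Ku(dna!+, cys~red) @ k_ku_red [repair]",
    "pk_bind: Ku(dna!+, cs!-) + DNAPKcs(ku!-, liIV!-) -> "
    "Ku(dna!+, cs!1) . DNAPKcs(ku!1, liIV!-) @ k_pk_bind [repair]",
    "pk_off: Ku(dna!+, cs!1) . DNAPKcs(ku!1, liIV!-) -> "
    "Ku(dna!+, cs!-) + DNAPKcs(ku!-, liIV!-) @ k_pk_off [repair]",
    "pk_autophos: DNAPKcs(ku!+, liIV!-, psite~u) -> DNAPKcs(ku!+, liIV!-, psite~p) @ k_pk_autophos [repair]",
    "pk_dephos_site: DNAPKcs(ku!+, liIV!-, psite~p) -> DNAPKcs(ku!+, liIV!-, psite~u) @ k_pk_dephos_site [repair]",
    "liIV_bind: DNAPKcs(ku!+, liIV!-, psite~p) + LiIV(cs!-) -> "
    "DNAPKcs(ku!+, liIV!1, psite~p) . LiIV(cs!1) @ k_liIV_bind [repair]",
    "liIV_off: DNAPKcs(ku!+, liIV!1) . LiIV(cs!1) -> DNAPKcs(ku!+, liIV!-) + LiIV(cs!-) @ k_liIV_off [repair]",
    "ligate_d_sdsb: DNA(site!1~sdsb, h2ax~foci) . Ku(dna!1, cs!2) . DNAPKcs(ku!2, liIV!3, psite~p) . LiIV(cs!3) -> "
    "DNA(site!-~ok, h2ax~foci) + Ku(dna!-, cs!-) + DNAPKcs(ku!-, liIV!-, psite~u) + LiIV(cs!-) @ k_lig_d_sdsb [repair]",
    "ligate_d_cdsb: DNA(site!1~cdsb, h2ax~foci) . Ku(dna!1, cs!2) . DNAPKcs(ku!2, liIV!3, psite~p) . LiIV(cs!3) -> "
    "DNA(site!-~ok, h2ax~foci) + Ku(dna!-, cs!-) + DNAPKcs(ku!-, liIV!-, psite~u) + LiIV(cs!-) @ k_lig_d_cdsb [repair]",
    "ox_breakup: DNA(site!1) . Ku(dna!1, cs!2, cys~ox) . DNAPKcs(ku!2, liIV!-) -> "
    "DNA(site!-) + Ku(dna!-, cs!-, cys~ox) + DNAPKcs(ku!-, liIV!-) @ k_ox_breakup [repair]",
    # B-NHEJ: PARP-1 -> ligase III
    "parp_bind: DNA(site!-~sdsb~cdsb) + PARP(dna!-, liIII!-) -> "
    "DNA(site!1~sdsb~cdsb) . PARP(dna!1, liIII!-) @ k_parp_bind [repair]",
    "parp_off: DNA(site!1) . PARP(dna!1, liIII!-) -> DNA(site!-) + PARP(dna!-, liIII!-) @ k_parp_off [repair]",
    "liIII_bind: PARP(dna!+, liIII!-) + LiIII(parp!-) -> PARP(dna!+, liIII!1) . LiIII(parp!1) @ k_liIII_bind [repair]",
    "liIII_off: PARP(dna!+, liIII!1) . LiIII(parp!1) -> PARP(dna!+, liIII!-) + LiIII(parp!-) @ k_liIII_off [repair]",
    "ligate_b_sdsb: DNA(site!1~sdsb, h2ax~foci) . PARP(dna!1, liIII!2) . LiIII(parp!2) -> "
    "DNA(site!-~ok, h2ax~foci) + PARP(dna!-, liIII!-) + LiIII(parp!-) @ k_lig_b_sdsb [repair]",
    "ligate_b_cdsb: DNA(site!1~cdsb, h2ax~foci) . PARP(dna!1, liIII!2) . LiIII(parp!2) -> "
    "DNA(site!-~ok, h2ax~foci) + PARP(dna!-, liIII!-) + LiIII(parp!-) @ k_lig_b_cdsb [repair]",
]

_POOL_RULES = [
    "ros_prod: Source_of_ROS() -> Source_of_ROS() + ROS() @ f_ros_prod [damage]",
    "ros_dec: ROS() -> 0 @ k_ros_dec [damage]",
    "atm_act: ATM(state~0, h2ax!-) -> ATM(state~1, h2ax!-) @ f_atm_act [signalling]",
    "atm_deact: ATM(state~1, h2ax!-) -> ATM(state~0, h2ax!-) @ k_atm_deact [signalling]",
    "p53_syn: p53_mRNA() -> p53_mRNA() + p53(psite~u) @ k_p53_syn [signalling]",
    "p53_deg: p53(psite~u) + MDM2(psite~u) -> MDM2(psite~u) @ k_p53_deg [signalling]",
    "p53_phos: p53(psite~u) + ATM(state~1, h2ax!-) -> p53(psite~p) + ATM(state~1, h2ax!-) @ k_p53_phos [signalling]",
    "p53_dephos: p53(psite~p) -> p53(psite~u) @ k_p53_dephos [signalling]",
    "mdm2_phos: MDM2(psite~u) + ATM(state~1, h2ax!-) -> MDM2(psite~p) + ATM(state~1, h2ax!-) @ k_mdm2_phos [signalling]",
    "mdm2p_deg: MDM2(psite~p) -> 0 @ k_mdm2p_deg [signalling]",
    "mdm2u_deg: MDM2(psite~u) -> 0 @ k_mdm2u_deg [signalling]",
    "mdm2_txn: 0 -> MDM2_mRNA() @ f_mdm2_txn [signalling]",
    "mdm2_mrna_dec: MDM2_mRNA() -> 0 @ k_mdm2_mrna_dec [signalling]",
    "mdm2_syn: MDM2_mRNA() -> MDM2_mRNA() + MDM2(psite~u) @ k_mdm2_syn [signalling]",
    "p21_txn: 0 -> p21_mRNA() @ f_p21_txn [signalling]",
    "p21_mrna_dec: p21_mRNA() -> 0 @ k_p21_mrna_dec [signalling]",
    "p21_syn: p21_mRNA() -> p21_mRNA() + P() @ k_p21_syn [signalling]",
    "p21_dec: P() -> 0 @ k_p21_dec [signalling]",
    "gadd_prod: 0 -> GADD45() @ f_gadd_prod [signalling]",
    "gadd_dec: GADD45() -> 0 @ k_gadd_dec [signalling]",
    "ku_dep: Ku(dna!-, cs!-, cys~red) -> 0 @ f_ku_dep [senescence]",
    "parp_dep: PARP(dna!-, liIII!-) -> 0 @ f_parp_dep [senescence]",
    # p21-driven senescence counter (PLUS / MINUS), irreversible switch at 10
    *[
        f"sen_plus_{i}: Sen(int~{i}, State~norm) -> Sen(int~{i + 1}, State~norm) @ f_sen_plus [senescence]"
        for i in range(1, 10)
    ],
    *[
        f"sen_minus_{i}: Sen(int~{i}, State~norm) -> Sen(int~{i - 1}, State~norm) @ f_sen_minus [senescence]"
        for i in range(2, 11)
    ],
    "sen_switch: Sen(int~10, State~norm) -> Sen(int~10, State~sen) @ k_sen_switch [senescence]",
]

_OBSERVABLES = {
    "ros": "ROS()",
    "p53_total": "p53()",
    "p21": "P()",
    "gadd45": "GADD45()",
    "n_broken": "DNA(site~sdsb~cdsb)",
    "ku_total": "Ku()",
    "parp_total": "PARP()",
    "sen_state": "Sen(State~sen)",
}

_FUNCTIONS = (
    RateFunction(
        "f_ros_prod", "threshold", "gadd45", "gt", "theta_gadd45_ros",
        "k_ros_prod_sen", "k_ros_prod_norm",
    ),
    RateFunction("f_atm_act", "linear", "n_broken", value_true="k_atm_act"),
    RateFunction(
        "f_mdm2_txn", "threshold", "p53_total", "gt", "theta_p53_mdm2",
        "k_mdm2_txn_hi", "k_mdm2_txn_lo",
    ),
    RateFunction(
        "f_p21_txn", "threshold", "p53_total", "gt", "theta_p53_p21",
        "k_p21_txn_hi", "k_p21_txn_lo",
    ),
    RateFunction(
        "f_gadd_prod", "threshold", "p21", "gt", "theta_p21_gadd",
        "k_gadd_prod_hi", "k_gadd_prod_lo",
    ),
    RateFunction(
        "f_sen_plus", "threshold", "p21", "gt", "theta_p21_sen", "k_sen_plus", 0.0
    ),
    RateFunction(
        "f_sen_minus", "threshold", "p21", "gt", "theta_p21_sen", 0.0, "k_sen_minus"
    ),
    RateFunction(
        "f_ku_bind", "threshold", "sen_state", "ge", 1.0, "k_ku_bind_sen", "k_ku_bind"
    ),
    RateFunction(
        "f_ku_dep", "threshold", "ku_total", "gt", "ku_floor", "k_ku_dep", 0.0,
        gate_obs="sen_state", gate_op="ge", gate_threshold=1.0,
    ),
    RateFunction(
        "f_parp_dep", "threshold", "parp_total", "gt", "parp_floor", "k_parp_dep", 0.0,
        gate_obs="sen_state", gate_op="ge", gate_threshold=1.0,
    ),
)

# Units: times in minutes, abundances in molecules per cell.
_PM = "1/min"  # per minute
_PMM = "1/(molecule*min)"  # per molecule per minute
_MOL = "molecules"

# (value, units, provenance) — provenance marks where the number conceptually
# comes from: the published NHEJ model, the published senescence model, a
# merged composite, a newly introduced reaction, or this package's
# calibration against the printed population statistics.
_BASE_PARAMS: dict[str, tuple[float, str, str]] = {
    # ROS background and feedback
    "k_ros_prod_norm": (2.0, _PM, "original-senescence"),
    "k_ros_prod_sen": (27.2263, _PM, "calibrated"),
    "theta_gadd45_ros": (20, _MOL, "calibrated"),
    "k_ros_dec": (0.01, _PM, "original-senescence"),
    # damage induction
    "k_dmg_sdsb": (8.28776e-07, _PMM, "calibrated"),
    "k_dmg_cdsb": (1.41381e-07, _PMM, "calibrated"),
    "k_complexify": (1.45169e-05, _PMM, "new"),
    "dsb_yield": (4.0, "breaks/Gy", "calibrated"),
    "fc_max": (0.864024, "fraction", "calibrated"),
    "fc_half": (0.5, "Gy", "calibrated"),
    # D-NHEJ
    "k_ku_bind": (2.0e-3, _PMM, "merged"),
    "k_ku_bind_sen": (6.0e-4, _PMM, "calibrated"),
    "k_ku_off_red": (0.02, _PM, "original-NHEJ"),
    "k_ku_off_ox": (0.2, _PM, "original-NHEJ"),
    "k_ku_ox": (5.0e-6, _PMM, "original-NHEJ"),
    "k_ku_red": (0.05, _PM, "original-NHEJ"),
    "k_pk_bind": (2.0e-3, _PMM, "merged"),
    "k_pk_off": (0.01, _PM, "original-NHEJ"),
    "k_pk_autophos": (0.3, _PM, "original-NHEJ"),
    "k_pk_dephos_site": (0.02, _PM, "new"),
    "k_liIV_bind": (5.0e-3, _PMM, "merged"),
    "k_liIV_off": (0.01, _PM, "original-NHEJ"),
    "k_lig_d_sdsb": (0.15, _PM, "original-NHEJ"),
    "k_lig_d_cdsb": (2.6e-3, _PM, "original-NHEJ"),
    "k_ox_breakup": (0.128388, _PM, "new"),
    # B-NHEJ
    "k_parp_bind": (2.0e-4, _PMM, "merged"),
    "k_parp_off": (0.02, _PM, "original-NHEJ"),
    "k_liIII_bind": (2.0e-3, _PMM, "merged"),
    "k_liIII_off": (0.02, _PM, "original-NHEJ"),
    "k_lig_b_sdsb": (0.03, _PM, "original-NHEJ"),
    "k_lig_b_cdsb": (1.0e-3, _PM, "original-NHEJ"),
    # foci
    "k_h2ax_phos_atm": (8.0e-3, _PMM, "merged"),
    "k_h2ax_phos_pk": (0.2, _PM, "new"),
    "k_h2ax_dephos": (0.05, _PM, "original-NHEJ"),
    "k_atm_bind": (5.0e-3, _PMM, "merged"),
    "k_focus_form": (0.5, _PM, "original-NHEJ"),
    "k_focus_res": (0.04, _PM, "original-NHEJ"),
    # ATM pool switch
    "k_atm_act": (0.012, _PMM, "original-senescence"),
    "k_atm_deact": (0.109429, _PM, "original-senescence"),
    # p53 / MDM2 oscillator
    "k_p53_syn": (0.0574, _PM, "original-senescence"),
    "k_p53_deg": (0.00157593, _PMM, "original-senescence"),
    "k_p53_phos": (0.00316033, _PMM, "original-senescence"),
    "k_p53_dephos": (0.0577, _PM, "original-senescence"),
    "k_mdm2_phos": (0.000243, _PMM, "original-senescence"),
    "k_mdm2p_deg": (0.1, _PM, "original-senescence"),
    "k_mdm2u_deg": (0.0129169, _PM, "original-senescence"),
    "k_mdm2_txn_lo": (0.335536, _PM, "original-senescence"),
    "k_mdm2_txn_hi": (31.3779, _PM, "calibrated"),
    "theta_p53_mdm2": (201.222, _MOL, "calibrated"),
    "k_mdm2_mrna_dec": (0.0145, _PM, "original-senescence"),
    "k_mdm2_syn": (0.0329332, _PM, "original-senescence"),
    # p21
    "k_p21_txn_lo": (0.005, _PM, "original-senescence"),
    "k_p21_txn_hi": (1, _PM, "calibrated"),
    "theta_p53_p21": (95, _MOL, "calibrated"),
    "k_p21_mrna_dec": (0.01, _PM, "original-senescence"),
    "k_p21_syn": (0.0493192, _PM, "original-senescence"),
    "k_p21_dec": (0.005, _PM, "original-senescence"),
    # GADD45 arm of the ROS feedback
    "k_gadd_prod_lo": (0.05, _PM, "original-senescence"),
    "k_gadd_prod_hi": (2, _PM, "calibrated"),
    "theta_p21_gadd": (650.0, _MOL, "calibrated"),
    "k_gadd_dec": (0.019974, _PM, "original-senescence"),
    # senescence counter and post-senescence depletion
    "k_sen_plus": (0.013, _PM, "calibrated"),
    "k_sen_minus": (0.0129039, _PM, "calibrated"),
    "theta_p21_sen": (766.442, _MOL, "calibrated"),
    "k_sen_switch": (10.0, _PM, "new"),
    "k_ku_dep": (0.005, _PM, "calibrated"),
    "ku_floor": (80.0, _MOL, "calibrated"),
    "k_parp_dep": (0.005, _PM, "calibrated"),
    "parp_floor": (50.0, _MOL, "calibrated"),
    # initial pool counts
    "init_ros": (200.0, _MOL, "original-senescence"),
    "init_ku": (400.0, _MOL, "original-NHEJ"),
    "init_pk": (300.0, _MOL, "original-NHEJ"),
    "init_liIV": (100.0, _MOL, "original-NHEJ"),
    "init_parp": (200.0, _MOL, "original-NHEJ"),
    "init_liIII": (100.0, _MOL, "original-NHEJ"),
    "init_atm": (200.0, _MOL, "original-senescence"),
    "init_p53": (28.0, _MOL, "original-senescence"),
    "init_mdm2": (31.0, _MOL, "original-senescence"),
    "init_mdm2_mrna": (41.0, _MOL, "original-senescence"),
    "init_p53_mrna": (20.0, _MOL, "original-senescence"),
    "init_p21_mrna": (0.0, _MOL, "original-senescence"),
    "init_p21": (0.0, _MOL, "original-senescence"),
    "init_gadd45": (3.0, _MOL, "original-senescence"),
    "init_p38u": (150.0, _MOL, "original-senescence"),
    "init_p38p": (50.0, _MOL, "original-senescence"),
}

_INITIAL_POOLS = {
    "Source_of_ROS()": 1.0,
    "ROS()": "init_ros",
    "Ku(dna!-, cs!-, cys~red)": "init_ku",
    "DNAPKcs(ku!-, liIV!-, psite~u)": "init_pk",
    "LiIV(cs!-)": "init_liIV",
    "PARP(dna!-, liIII!-)": "init_parp",
    "LiIII(parp!-)": "init_liIII",
    "ATM(state~0, h2ax!-)": "init_atm",
    "p53_mRNA()": "init_p53_mrna",
    "p53(psite~u)": "init_p53",
    "MDM2(psite~u)": "init_mdm2",
    "MDM2_mRNA()": "init_mdm2_mrna",
    "p21_mRNA()": "init_p21_mrna",
    "P()": "init_p21",
    "GADD45()": "init_gadd45",
    "p38(psite~u)": "init_p38u",
    "p38(psite~p)": "init_p38p",
    "Sen(int~1, State~norm)": 1.0,
}

# preset-specific parameter overrides
_PRESET_OVERRIDES: dict[str, dict[str, float]] = {
    "MRC5": {},
    # MCF7 cells are more senescence-resistant: only the rate at which p21
    # advances the senescence counter differs.
    "MCF7": {"k_sen_plus": 0.010},
    # variant with ~4x higher steady-state p53 abundance: production and
    # degradation jointly rescaled, p53-read thresholds shifted accordingly
    # so downstream senescence behaviour is preserved.
    "high_p53": {
        "k_p53_syn": 0.344,
        "k_p53_deg": 2.36e-3,
        "theta_p53_mdm2": 805.0,
        "theta_p53_p21": 380.0,
        "init_p53": 112.0,
    },
}


def build_default_model(
    preset: str = "MRC5", n_dna_sites: int = N_DNA_SITES_DEFAULT
) -> ModelSpec:
    """Construct and validate the integrated model for a named preset.

    Parameters
    ----------
    preset:
        ``MRC5`` (fibroblast calibration, the default), ``MCF7``
        (senescence-resistant variant differing only in the p21->senescence
        accumulation rate) or ``high_p53`` (rescaled p53 turnover giving a
        higher unirradiated p53 steady state).
    n_dna_sites:
        Number of independent DNA break sites (50 in the full model;
        reduced values are useful for exhaustive network checks).
    """
    if preset not in PRESETS:
        raise ModelValidationError(
            f"unknown preset {preset!r}; expected one of {PRESETS}"
        )
    params = ParameterSet(
        {k: ParamEntry(v, u, p) for k, (v, u, p) in _BASE_PARAMS.items()}
    )
    for k, v in _PRESET_OVERRIDES[preset].items():
        params[k] = replace(params[k], value=v)
    initial = {
        k: (v if isinstance(v, str) else v) for k, v in _INITIAL_POOLS.items()
    }
    model = ModelSpec(
        preset=preset,
        molecules=_molecules(n_dna_sites),
        rules=tuple(parse_rule(r) for r in (*_SITE_RULES, *_POOL_RULES)),
        functions=_FUNCTIONS,
        parameters=params,
        observables=dict(_OBSERVABLES),
        initial_pools=initial,
        n_dna_sites=n_dna_sites,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# serialization (structured text with [molecules]/[rules]/[functions]/[parameters])
# ---------------------------------------------------------------------------


def save_model(model: ModelSpec, path: str | Path) -> None:
    """Write a model to a structured YAML file (round-trips bit-exact)."""
    doc = {
        "preset": model.preset,
        "n_dna_sites": model.n_dna_sites,
        "molecules": {
            m.name: {
                c.name: {"states": list(c.states), "binds": c.binds}
                for c in m.components
            }
            for m in model.molecules
        },
        "rules": [r.text for r in model.rules],
        "functions": [
            {
                k: v
                for k, v in {
                    "name": f.name,
                    "kind": f.kind,
                    "obs": f.obs,
                    "op": f.op,
                    "threshold": f.threshold,
                    "value_true": f.value_true,
                    "value_false": f.value_false,
                    "gate_obs": f.gate_obs,
                    "gate_op": f.gate_op,
                    "gate_threshold": f.gate_threshold,
                }.items()
                if v is not None
            }
            for f in model.functions
        ],
        "observables": dict(model.observables),
        "initial": dict(model.initial_pools),
        "parameters": {
            k: {"value": e.value, "units": e.units, "provenance": e.provenance}
            for k, e in model.parameters.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> ModelSpec:
    """Read a model file written by :func:`save_model` and validate it."""
    doc = yaml.safe_load(Path(path).read_text())
    molecules = tuple(
        MoleculeSpec(
            name,
            tuple(
                ComponentSpec(cname, tuple(cdef["states"]), cdef["binds"])
                for cname, cdef in comps.items()
            ),
        )
        for name, comps in doc["molecules"].items()
    )
    functions = tuple(RateFunction(**f) for f in doc["functions"])
    params = ParameterSet(
        {
            k: ParamEntry(e["value"], e["units"], e["provenance"])
            for k, e in doc["parameters"].items()
        }
    )
    model = ModelSpec(
        preset=doc["preset"],
        molecules=molecules,
        rules=tuple(parse_rule(r) for r in doc["rules"]),
        functions=functions,
        parameters=params,
        observables=doc["observables"],
        initial_pools=doc["initial"],
        n_dna_sites=doc["n_dna_sites"],
    )
    model.validate()
    return model
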