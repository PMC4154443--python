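"""Declarative AII contact rules and the connectivity auditor.

AII amacrine cells make or decline connections by stereotyped,
compartment-specific rules: arboreal dendrites are always postsynaptic to
rod bipolar cells and never presynaptic; gap junctions are made with every
encountered ON cone bipolar cell but never with rod or OFF bipolar cells;
lobules are the sole output compartment; ribbon input from ON cone bipolar
cells is forbidden except for the CBb7 class; every lobule encountered by an
OFF alpha/delta ganglion cell dendrite is presynaptic to it; arboreal
touches with ganglion cells, and lobule contacts with AI cells, carry no
specializations.

The auditor classifies every resolved contact against the rule table and
counts proper connections and violations; ``required_on_encounter`` rules
are additionally audited over cell pairs that carry at least one touch or
specialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import resolve_contacts
from .model import AnnotationDB, ContactPair, in_group

__all__ = [
    "Rule",
    "RuleViolation",
    "RuleSet",
    "ValidationReport",
    "default_ruleset",
    "validate",
    "encounter_audit",
]

_SYNAPSE_KINDS = ("ribbon_input", "conventional_synapse")
_SPECIALIZATION_KINDS = ("ribbon_input", "conventional_synapse",
                         "gap_junction", "adherens")
#: kinds counted as connections (touches are non-connections)
_CONNECTION_KINDS = _SPECIALIZATION_KINDS


@dataclass(frozen=True)
class Rule:
    rule_id: str
    focal_class: str
    partner_class: str  # class name, group name, or 'any'
    focal_compartment: tuple[str, ...] | str  # compartment(s) or 'any'
    kind: tuple[str, ...] | str  # contact kind(s) or 'any_specialization'
    mode: str  # 'required_on_encounter' | 'permitted' | 'forbidden'
    direction: str  # 'focal_pre' | 'focal_post' | 'symmetric' | 'any'
    note: str = ""

    def kinds(self) -> tuple[str, ...]:
        if self.kind == "any_specialization":
            return _SPECIALIZATION_KINDS
        if isinstance(self.kind, str):
            return (self.kind,)
        return self.kind

    def compartments(self) -> tuple[str, ...] | None:
        if self.focal_compartment == "any":
            return None
        if isinstance(self.focal_compartment, str):
            return (self.focal_compartment,)
        return self.focal_compartment


@dataclass(frozen=True)
class RuleViolation:
    rule_id: str
    description: str
    pre_cell: int
    post_cell: int
    pre_structure: int | None = None
    post_structure: int | None = None


@dataclass
class RuleSet:
    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [
            (r.focal_class, r.partner_class, r.focal_compartment, r.kind,
             r.direction)
            for r in self.rules
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate rule keys in ruleset")
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rule ids in ruleset")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def get(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def required_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.mode == "required_on_encounter"]

    def match(
        self,
        partner_class: str,
        focal_compartment: str,
        kind: str,
        direction: str,
    ) -> Rule | None:
        """Most specific rule matching an AII-focal contact view.

        Specificity ranks exact partner class above group above wildcard,
        plus one point each for a specific compartment and direction; on a
        specificity tie, forbidden outranks required outranks permitted.
        """
        best: tuple[int, int] | None = None
        best_rule: Rule | None = None
        mode_rank = {"forbidden": 2, "required_on_encounter": 1,
                     "permitted": 0}
        for r in self.rules:
            if kind not in r.kinds():
                continue
            comps = r.compartments()
            if comps is not None and focal_compartment not in comps:
                continue
            if r.direction != "any" and direction != r.direction:
                continue
            if not in_group(partner_class, r.partner_class):
                continue
            if r.partner_class == "any":
                p_spec = 0
            elif partner_class == r.partner_class:
                p_spec = 2
            else:
                p_spec = 1  # group match
            spec = (
                3 * p_spec
                + (1 if comps is not None else 0)
                + (1 if r.direction != "any" else 0)
            )
            key = (spec, mode_rank[r.mode])
            if best is None or key > best:
                best = key
                best_rule = r
        return best_rule

    def to_json(self, path: str | Path) -> None:
        data = [
            {
                "rule_id": r.rule_id,
                "focal_class": r.focal_class,
                "partner_class": r.partner_class,
                "focal_compartment": list(r.focal_compartment)
                if isinstance(r.focal_compartment, tuple)
                else r.focal_compartment,
                "kind": list(r.kind) if isinstance(r.kind, tuple) else r.kind,
                "mode": r.mode,
                "direction": r.direction,
                "note": r.note,
            }
            for r in self.rules
        ]
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSet":
        data = json.loads(Path(path).read_text())
        rules = []
        for d in data:
            for key in ("focal_compartment", "kind"):
                if isinstance(d[key], list):
                    d[key] = tuple(d[key])
            rules.append(Rule(**d))
        return cls(rules=rules)


def default_ruleset() -> RuleSet:
    """The AII contact-rule table.

    Directions are relative to the focal AII cell; compartments are the
    focal AII compartments at which the rule applies.
    """
    R = Rule
    return RuleSet(rules=[
        R("rod-ribbon-arboreal", "AII", "RodBC", "arboreal", "ribbon_input",
          "required_on_encounter", "focal_post",
          "arboreal dendrites always accept rod bipolar ribbons"),
        R("no-rod-gj", "AII", "RodBC", "any", "gap_junction",
          "forbidden", "symmetric",
          "never gap junctions with rod bipolar cells"),
        R("no-presyn-to-rod", "AII", "RodBC", "any", _SYNAPSE_KINDS,
          "forbidden", "focal_pre",
          "never presynaptic to rod bipolar cells"),
        R("no-rod-ribbon-lobule", "AII", "RodBC", "lobule", "ribbon_input",
          "forbidden", "focal_post",
          "rod axons in transit past lobules form no ribbons"),
        R("aii-coupling-arboreal", "AII", "AII", "arboreal", "gap_junction",
          "required_on_encounter", "symmetric",
          "arboreal AII::AII encounters always couple"),
        R("aii-coupling-waist", "AII", "AII", "waist", "gap_junction",
          "permitted", "symmetric"),
        R("no-aii-coupling-lobule", "AII", "AII", "lobule", "gap_junction",
          "forbidden", "symmetric",
          "connexins are excluded from lobules"),
        R("cbb-coupling-arboreal", "AII", "CBb", "arboreal", "gap_junction",
          "required_on_encounter", "symmetric",
          "every encountered ON cone bipolar cell is coupled"),
        R("cbb-coupling-waist", "AII", "CBb", "waist", "gap_junction",
          "permitted", "symmetric"),
        R("no-cbb-coupling-lobule", "AII", "CBb", "lobule", "gap_junction",
          "forbidden", "symmetric",
          "ON cone bipolar axons touching lobules never couple"),
        R("no-cba-gj", "AII", "CBa", "any", "gap_junction",
          "forbidden", "symmetric",
          "never gap junctions with OFF cone bipolar cells"),
        R("no-cbb-ribbon", "AII", "CBb_non7", "any", "ribbon_input",
          "forbidden", "focal_post",
          "ON cone bipolar ribbon input forbidden except CBb7"),
        R("cbb7-ribbon", "AII", "CBb7", ("waist", "arboreal"),
          "ribbon_input", "permitted", "focal_post",
          "CBb7 uniquely makes both ribbons and gap junctions"),
        R("cba-ribbon-lobule", "AII", "CBa", "lobule", "ribbon_input",
          "permitted", "focal_post",
          "sparse OFF bipolar ribbon input onto lobules"),
        R("output-to-cba", "AII", "CBa", "lobule", "conventional_synapse",
          "permitted", "focal_pre"),
        R("outputs-only-lobules", "AII", "any",
          ("neck", "waist", "arboreal"), "conventional_synapse",
          "forbidden", "focal_pre",
          "synaptic output is restricted to lobules"),
        R("no-aii-ribbons", "AII", "any", "any", "ribbon_input",
          "forbidden", "focal_pre",
          "AII cells make no ribbon synapses"),
        R("th1-neck-input", "AII", "TH1", ("neck", "lobule"),
          "conventional_synapse", "permitted", "focal_post",
          "dopaminergic/glutamatergic TH1 input onto the neck"),
        R("ac-input", "AII", "AC", "any", "conventional_synapse",
          "permitted", "focal_post",
          "GABAergic/glycinergic amacrine input"),
        R("no-ai-synapse-lobule", "AII", "AI", "lobule",
          _SYNAPSE_KINDS, "forbidden", "any",
          "lobule encounters with AI processes are never synaptic"),
        R("output-to-ac", "AII", "AC", "lobule", "conventional_synapse",
          "permitted", "focal_pre"),
        R("gc-output-on-encounter", "AII", "GC", "lobule",
          "conventional_synapse", "required_on_encounter", "focal_pre",
          "every lobule encountered by an OFF alpha/delta ganglion cell "
          "dendrite makes a synapse"),
        R("no-arboreal-gc-contact", "AII", "GC", ("waist", "arboreal"),
          "any_specialization", "forbidden", "any",
          "arboreal touches with ganglion cells make no specializations"),
        R("adherens-ok", "AII", "any", "any", "adherens",
          "permitted", "symmetric"),
        R("touch-ok", "AII", "any", "any", "touch",
          "permitted", "symmetric"),
    ])


@dataclass
class ValidationReport:
    n_proper: int
    n_out_of_scope: int
    n_excluded_unknown: int
    n_touches: int
    violations: list[RuleViolation]
    encounter_table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def _views(c: ContactPair, db: AnnotationDB):
    """AII-focal views of a contact: (focal_cell, partner_cell,
    partner_class, focal_compartment, direction).  A homocellular AII::AII
    contact yields a single symmetric view."""
    pre_class = db.cell_class(c.pre_cell)
    post_class = db.cell_class(c.post_cell)
    symmetric = c.kind in ("gap_junction", "adherens", "touch")
    views = []
    if pre_class == "AII":
        direction = "symmetric" if symmetric else "focal_pre"
        views.append((c.pre_cell, c.post_cell, post_class,
                      c.pre_compartment, direction))
    if post_class == "AII" and not (pre_class == "AII" and symmetric):
        direction = "symmetric" if symmetric else "focal_post"
        views.append((c.post_cell, c.pre_cell, pre_class,
                      c.post_compartment, direction))
    return views


def validate(
    db: AnnotationDB,
    ruleset: RuleSet | None = None,
    contacts: list[ContactPair] | None = None,
) -> ValidationReport:
    """Audit every resolved contact against the rule table.

    Connections (ribbon, conventional, gap junction, adherens) involving an
    AII cell are each matched to the most specific rule: forbidden matches
    and unmatched connections are violations, everything else is proper.
    ``required_on_encounter`` rules are then audited over cell pairs
    carrying at least one touch or specialization.  Cells of unknown class
    are excluded with a warning; contacts not involving an AII cell are
    counted as out of scope.
    """
    if ruleset is None:
        ruleset = default_ruleset()
    if contacts is None:
        contacts = resolve_contacts(db)

    violations: list[RuleViolation] = []
    warnings: list[str] = []
    n_proper = 0
    n_out_of_scope = 0
    n_excluded = 0
    n_touches = 0

    for c in contacts:
        pre_class = db.cell_class(c.pre_cell)
        post_class = db.cell_class(c.post_cell)
        if "other" in (pre_class, post_class):
            n_excluded += 1
            warnings.append(
                f"contact ({c.pre_structure}, {c.post_structure}) involves "
                "an unclassified cell; excluded from audit"
            )
            continue
        if c.kind == "touch":
            n_touches += 1
            continue
        views = _views(c, db)
        if not views:
            n_out_of_scope += 1
            continue
        contact_ok = True
        for focal, partner, partner_class, comp, direction in views:
            rule = ruleset.match(partner_class, comp, c.kind, direction)
            if rule is None:
                violations.append(RuleViolation(
                    rule_id="unmatched",
                    description=(
                        f"{c.kind} between AII {focal} ({comp}) and "
                        f"{partner_class} {partner} matches no rule"
                    ),
                    pre_cell=c.pre_cell, post_cell=c.post_cell,
                    pre_structure=c.pre_structure,
                    post_structure=c.post_structure,
                ))
                contact_ok = False
            elif rule.mode == "forbidden":
                violations.append(RuleViolation(
                    rule_id=rule.rule_id,
                    description=(
                        f"{c.kind} between AII {focal} ({comp}) and "
                        f"{partner_class} {partner} violates "
                        f"'{rule.rule_id}'"
                    ),
                    pre_cell=c.pre_cell, post_cell=c.post_cell,
                    pre_structure=c.pre_structure,
                    post_structure=c.post_structure,
                ))
                contact_ok = False
        if contact_ok:
            n_proper += 1

    table, enc_violations = _audit_encounters(db, ruleset, contacts)
    violations.extend(enc_violations)

    return ValidationReport(
        n_proper=n_proper,
        n_out_of_scope=n_out_of_scope,
        n_excluded_unknown=n_excluded,
        n_touches=n_touches,
        violations=violations,
        encounter_table=table,
        warnings=warnings,
    )


def _audit_encounters(
    db: AnnotationDB, ruleset: RuleSet, contacts: list[ContactPair]
):
    """Evaluate required_on_encounter rules over cell pairs that carry at
    least one touch or specialization in the rule's focal compartment."""
    rows = []
    violations: list[RuleViolation] = []
    for rule in ruleset.required_rules():
        comps = rule.compartments()
        encounters: set[tuple[int, int]] = set()
        honored: set[tuple[int, int]] = set()
        for c in contacts:
            for focal, partner, partner_class, comp, direction in _views(
                c, db
            ):
                if not in_group(partner_class, rule.partner_class):
                    continue
                if comps is not None and comp not in comps:
                    continue
                pair = (focal, partner)
                encounters.add(pair)
                if c.kind in rule.kinds() and (
                    rule.direction == "any" or direction == rule.direction
                ):
                    honored.add(pair)
        for pair in sorted(encounters - honored):
            violations.append(RuleViolation(
                rule_id=rule.rule_id,
                description=(
                    f"encounter between AII {pair[0]} and cell {pair[1]} "
                    f"lacks the required {rule.kinds()[0]} "
                    f"('{rule.rule_id}')"
                ),
                pre_cell=pair[0], post_cell=pair[1],
            ))
        rows.append({
            "rule_id": rule.rule_id,
            "encounters": len(encounters),
            "honored": len(honored),
            "violated": len(encounters) - len(honored),
        })
    return pd.DataFrame(rows), violations


def encounter_audit(
    db: AnnotationDB,
    ruleset: RuleSet | None = None,
    contacts: list[ContactPair] | None = None,
) -> pd.DataFrame:
    """Encounter counts per required_on_encounter rule
    (honored + violated = encounters)."""
    if ruleset is None:
        ruleset = default_ruleset()
    if contacts is None:
        contacts = resolve_contacts(db)
    table, _ = _audit_encounters(db, ruleset, contacts)
    return table
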