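"""Parsing, validation and packaging of SMARTS-encoded reaction definitions.

A reaction definition couples *synthons* (reagent classes given by inclusion
SMARTS, optional synthon-specific exclusions, an optional symmetry pattern and
reaction tags) with ordered *transform variants* (atom-mapped reaction SMARTS
whose component tags select which synthon feeds each reagent slot).

Definitions live in a line-oriented two-file text format:

``<NAME>_Reagents.txt`` — tab-separated fields, leading record-type token:

=========  ==========================================================
record     fields
=========  ==========================================================
SYNTHON    synthon_id, inclusion SMARTS (``|``-separated alternatives)
EXCLUDE    synthon_id or ``*`` (reaction-global), exclusion SMARTS
SYMMETRIC  synthon_id, SMARTS identifying symmetric reagents
TAG        synthon_id, comma-separated reaction tags
PRECURSOR  synthon_id, one-component transform SMARTS (repeatable);
           marks the synthon as a purchasable precursor of another class
=========  ==========================================================

``<NAME>_Reactions.txt``:

=========  ==========================================================
REACTION   variant_id, transform SMARTS, comma-separated component
           tags (reagent order), optional ``key=value`` annotations
=========  ==========================================================

Blank lines and ``#`` comments are ignored. The printed-glyph arrow ``⨠``
is normalized to the conventional ``>>`` separator at parse time.

Six reaction definitions ship with the package (:func:`builtin_library`):
beta-keto-imides, 5-amino-thiatriazoles, 5-amino-tetrazoles, the
Truce-Smiles rearrangement, and the [2+2]- and [4+2]-cycloadditions.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from importlib import resources
from typing import Iterable

from rdkit import Chem

from ._chem import ChemistryError, reaction_from_smarts, smarts_query

ARROW = ">>"
_PRINTED_ARROW = "⨠"  # ⨠, a typographic stand-in for ">>"

_REAGENT_TOKENS = ("SYNTHON", "EXCLUDE", "SYMMETRIC", "TAG", "PRECURSOR")


class ReactionParseError(ValueError):
    """Raised on malformed definition files; carries a 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        where = f"line {line_no}: " if line_no is not None else ""
        super().__init__(where + message)


def normalize_transform(transform: str) -> str:
    return transform.replace(_PRINTED_ARROW, ARROW).strip()


# ---------------------------------------------------------------------------
# domain types


@dataclasses.dataclass(frozen=True)
class SynthonDefinition:
    """One reagent class: what qualifies, what is vetoed, how it plugs in."""

    synthon_id: str
    inclusion_patterns: tuple[str, ...]
    reaction_tags: tuple[str, ...]
    exclusion_patterns: tuple[str, ...] = ()
    symmetric_pattern: str | None = None
    is_precursor: bool = False
    precursor_transforms: tuple[str, ...] = ()


@dataclasses.dataclass(frozen=True)
class ReactionVariant:
    """One atom-mapped transform with its ordered reagent slots."""

    variant_id: str
    transform: str
    component_tags: tuple[str, ...]
    annotations: tuple[tuple[str, str], ...] = ()

    @property
    def arity(self) -> int:
        return len(self.component_tags)

    @property
    def annotation_dict(self) -> dict[str, str]:
        return dict(self.annotations)


@dataclasses.dataclass(frozen=True)
class ReactionDefinition:
    """A named reaction: synthons, ordered variants, reaction-global exclusions."""

    reaction_id: str
    display_name: str
    synthons: tuple[SynthonDefinition, ...]
    variants: tuple[ReactionVariant, ...]
    global_exclusions: tuple[str, ...] = ()

    def synthon(self, synthon_id: str) -> SynthonDefinition:
        for syn in self.synthons:
            if syn.synthon_id == synthon_id:
                return syn
        raise KeyError(synthon_id)

    def resolve_tag(self, tag: str) -> SynthonDefinition:
        """The unique non-precursor synthon carrying ``tag``."""
        hits = [s for s in self.synthons if not s.is_precursor and tag in s.reaction_tags]
        if len(hits) != 1:
            raise KeyError(f"tag {tag!r} resolves to {len(hits)} synthons")
        return hits[0]

    def precursors_for_tag(self, tag: str) -> tuple[SynthonDefinition, ...]:
        """Precursor synthons whose expansion feeds the slot named ``tag``."""
        return tuple(s for s in self.synthons if s.is_precursor and tag in s.reaction_tags)


@dataclasses.dataclass
class ValidationReport:
    issues: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(severity == "error" for severity, _, _ in self.issues)

    def add(self, severity: str, location: str, message: str) -> None:
        self.issues.append((severity, location, message))

    def errors(self) -> list[tuple[str, str, str]]:
        return [i for i in self.issues if i[0] == "error"]


# ---------------------------------------------------------------------------
# parsing


def _records(text: str) -> Iterable[tuple[int, list[str]]]:
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield line_no, [f.strip() for f in line.split("\t")]


def _check_smarts(pattern: str, line_no: int) -> None:
    try:
        smarts_query(pattern)
    except ChemistryError:
        raise ReactionParseError(f"malformed SMARTS {pattern!r}", line_no) from None


def _check_transform(transform: str, line_no: int):
    try:
        return reaction_from_smarts(transform)
    except ChemistryError:
        raise ReactionParseError(f"malformed reaction SMARTS {transform!r}", line_no) from None


def _transform_map_balance(rxn) -> set[int]:
    """Product-side atom maps that never appear on the reagent side."""
    reagent_maps: set[int] = set()
    for i in range(rxn.GetNumReactantTemplates()):
        for atom in rxn.GetReactantTemplate(i).GetAtoms():
            if atom.GetAtomMapNum():
                reagent_maps.add(atom.GetAtomMapNum())
    orphan: set[int] = set()
    for i in range(rxn.GetNumProductTemplates()):
        for atom in rxn.GetProductTemplate(i).GetAtoms():
            num = atom.GetAtomMapNum()
            if num and num not in reagent_maps:
                orphan.add(num)
    return orphan


def parse_synthon_file(text: str) -> list[SynthonDefinition]:
    """Parse a ``*_Reagents.txt`` body into synthon definitions.

    Reaction-global ``EXCLUDE *`` records are legal in the same file but are
    not part of any synthon; retrieve them with :func:`parse_global_exclusions`.
    Unknown record types and malformed SMARTS raise :class:`ReactionParseError`
    naming the offending line.
    """
    if not text.strip():
        raise ReactionParseError("empty reagents file")

    order: list[str] = []
    inclusions: dict[str, tuple[str, ...]] = {}
    exclusions: dict[str, list[str]] = {}
    symmetric: dict[str, str] = {}
    tags: dict[str, tuple[str, ...]] = {}
    precursors: dict[str, list[str]] = {}

    for line_no, fields in _records(text):
        token = fields[0]
        if token not in _REAGENT_TOKENS:
            raise ReactionParseError(f"unknown record type {token!r}", line_no)
        if len(fields) < 3:
            raise ReactionParseError(f"{token} record needs 3 fields, got {len(fields)}", line_no)
        syn_id, payload = fields[1], fields[2]

        if token == "SYNTHON":
            if syn_id in inclusions:
                raise ReactionParseError(f"duplicate synthon_id {syn_id!r}", line_no)
            patterns = tuple(p.strip() for p in payload.split("|") if p.strip())
            if not patterns:
                raise ReactionParseError("SYNTHON record with no patterns", line_no)
            for p in patterns:
                _check_smarts(p, line_no)
            inclusions[syn_id] = patterns
            order.append(syn_id)
        elif token == "EXCLUDE":
            if syn_id == "*":
                _check_smarts(payload, line_no)
                continue  # reaction-global; see parse_global_exclusions
            _check_smarts(payload, line_no)
            exclusions.setdefault(syn_id, []).append(payload)
        elif token == "SYMMETRIC":
            if syn_id in symmetric:
                raise ReactionParseError(f"duplicate SYMMETRIC for {syn_id!r}", line_no)
            _check_smarts(payload, line_no)
            symmetric[syn_id] = payload
        elif token == "TAG":
            if syn_id in tags:
                raise ReactionParseError(f"duplicate TAG record for {syn_id!r}", line_no)
            tag_list = tuple(t.strip() for t in payload.split(",") if t.strip())
            if not tag_list:
                raise ReactionParseError("TAG record with no tags", line_no)
            tags[syn_id] = tag_list
        elif token == "PRECURSOR":
            transform = normalize_transform(payload)
            rxn = _check_transform(transform, line_no)
            if rxn.GetNumReactantTemplates() != 1:
                raise ReactionParseError("precursor transform must be one-component", line_no)
            precursors.setdefault(syn_id, []).append(transform)

    for mapping, what in ((exclusions, "EXCLUDE"), (symmetric, "SYMMETRIC"),
                          (tags, "TAG"), (precursors, "PRECURSOR")):
        for syn_id in mapping:
            if syn_id not in inclusions:
                raise ReactionParseError(f"{what} references undeclared synthon {syn_id!r}")

    out = []
    for syn_id in order:
        if syn_id not in tags:
            raise ReactionParseError(f"synthon {syn_id!r} has no TAG record")
        out.append(SynthonDefinition(
            synthon_id=syn_id,
            inclusion_patterns=inclusions[syn_id],
            reaction_tags=tags[syn_id],
            exclusion_patterns=tuple(exclusions.get(syn_id, ())),
            symmetric_pattern=symmetric.get(syn_id),
            is_precursor=syn_id in precursors,
            precursor_transforms=tuple(precursors.get(syn_id, ())),
        ))
    return out


def parse_global_exclusions(text: str) -> list[str]:
    """``EXCLUDE *`` patterns of a reagents file, in file order."""
    out = []
    for line_no, fields in _records(text):
        if fields[0] == "EXCLUDE" and len(fields) >= 3 and fields[1] == "*":
            _check_smarts(fields[2], line_no)
            out.append(fields[2])
    return out


def parse_reaction_file(text: str) -> list[ReactionVariant]:
    """Parse a ``*_Reactions.txt`` body into ordered transform variants.

    The transform must parse, product-side atom maps must all appear on the
    reagent side, and the number of component tags must equal the number of
    reagent templates. Tags referencing no synthon are deferred to
    :func:`validate` (the reagents file is not in view here).
    """
    variants: list[ReactionVariant] = []
    seen_ids: set[str] = set()
    for line_no, fields in _records(text):
        if fields[0] != "REACTION":
            raise ReactionParseError(f"unknown record type {fields[0]!r}", line_no)
        if len(fields) < 4:
            raise ReactionParseError(
                f"REACTION record needs >=4 fields, got {len(fields)}", line_no)
        variant_id = fields[1]
        if variant_id in seen_ids:
            raise ReactionParseError(f"duplicate variant_id {variant_id!r}", line_no)
        seen_ids.add(variant_id)
        transform = normalize_transform(fields[2])
        rxn = _check_transform(transform, line_no)
        orphan = _transform_map_balance(rxn)
        if orphan:
            raise ReactionParseError(
                f"product atom maps {sorted(orphan)} absent from reagent side", line_no)
        component_tags = tuple(t.strip() for t in fields[3].split(",") if t.strip())
        if len(component_tags) != rxn.GetNumReactantTemplates():
            raise ReactionParseError(
                f"{len(component_tags)} component tags for "
                f"{rxn.GetNumReactantTemplates()} reagent templates", line_no)
        annotations: tuple[tuple[str, str], ...] = ()
        if len(fields) >= 5 and fields[4]:
            pairs = []
            for item in fields[4].split(","):
                if "=" not in item:
                    raise ReactionParseError(f"annotation {item!r} is not key=value", line_no)
                k, v = item.split("=", 1)
                pairs.append((k.strip(), v.strip()))
            annotations = tuple(pairs)
        variants.append(ReactionVariant(variant_id, transform, component_tags, annotations))
    return variants


# ---------------------------------------------------------------------------
# serialization (round-trips with the parsers)


def serialize_synthons(synthons: Iterable[SynthonDefinition],
                       global_exclusions: Iterable[str] = ()) -> str:
    lines = []
    for syn in synthons:
        lines.append(f"SYNTHON\t{syn.synthon_id}\t{'|'.join(syn.inclusion_patterns)}")
        if syn.symmetric_pattern:
            lines.append(f"SYMMETRIC\t{syn.synthon_id}\t{syn.symmetric_pattern}")
        for pattern in syn.exclusion_patterns:
            lines.append(f"EXCLUDE\t{syn.synthon_id}\t{pattern}")
        for transform in syn.precursor_transforms:
            lines.append(f"PRECURSOR\t{syn.synthon_id}\t{transform}")
        lines.append(f"TAG\t{syn.synthon_id}\t{','.join(syn.reaction_tags)}")
    for pattern in global_exclusions:
        lines.append(f"EXCLUDE\t*\t{pattern}")
    return "\n".join(lines) + "\n"


def serialize_variants(variants: Iterable[ReactionVariant]) -> str:
    lines = []
    for var in variants:
        fields = ["REACTION", var.variant_id, var.transform, ",".join(var.component_tags)]
        if var.annotations:
            fields.append(",".join(f"{k}={v}" for k, v in var.annotations))
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def serialize(defn: ReactionDefinition) -> tuple[str, str]:
    """(reagents-file text, reactions-file text) for a definition."""
    return (serialize_synthons(defn.synthons, defn.global_exclusions),
            serialize_variants(defn.variants))


def load_definition(reaction_id: str, display_name: str,
                    reagents_text: str, reactions_text: str) -> ReactionDefinition:
    return ReactionDefinition(
        reaction_id=reaction_id,
        display_name=display_name,
        synthons=tuple(parse_synthon_file(reagents_text)),
        variants=tuple(parse_reaction_file(reactions_text)),
        global_exclusions=tuple(parse_global_exclusions(reagents_text)),
    )


# ---------------------------------------------------------------------------
# validation


def validate(defn: ReactionDefinition) -> ValidationReport:
    """Consistency report for a definition. Pure: never mutates, never raises.

    Errors: unparseable SMARTS/transforms, component tags that resolve to
    zero or several non-precursor synthons, arity mismatches, product-side
    atom maps missing from the reagent side. Warnings: synthons never
    referenced by any variant.
    """
    report = ValidationReport()

    for syn in defn.synthons:
        loc = f"synthon {syn.synthon_id}"
        if not syn.synthon_id:
            report.add("error", loc, "empty synthon_id")
        if not syn.reaction_tags:
            report.add("error", loc, "no reaction tags")
        for pattern in syn.inclusion_patterns + syn.exclusion_patterns:
            try:
                smarts_query(pattern)
            except ChemistryError:
                report.add("error", loc, f"malformed SMARTS {pattern!r}")
        if syn.symmetric_pattern:
            try:
                smarts_query(syn.symmetric_pattern)
            except ChemistryError:
                report.add("error", loc, f"malformed SMARTS {syn.symmetric_pattern!r}")
        if syn.is_precursor and not syn.precursor_transforms:
            report.add("error", loc, "precursor flag without transforms")
        for transform in syn.precursor_transforms:
            try:
                reaction_from_smarts(transform)
            except ChemistryError:
                report.add("error", loc, f"malformed transform {transform!r}")

    ids = [s.synthon_id for s in defn.synthons]
    for dup in {i for i in ids if ids.count(i) > 1}:
        report.add("error", f"synthon {dup}", "duplicate synthon_id")

    for pattern in defn.global_exclusions:
        try:
            smarts_query(pattern)
        except ChemistryError:
            report.add("error", "global exclusions", f"malformed SMARTS {pattern!r}")

    if not defn.variants:
        report.add("error", "variants", "no variants defined")

    used_tags: set[str] = set()
    for var in defn.variants:
        loc = f"variant {var.variant_id}"
        try:
            rxn = reaction_from_smarts(var.transform)
        except ChemistryError:
            report.add("error", loc, f"malformed transform {var.transform!r}")
            continue
        orphan = _transform_map_balance(rxn)
        if orphan:
            report.add("error", loc,
                       f"product atom maps {sorted(orphan)} absent from reagent side")
        if rxn.GetNumReactantTemplates() != var.arity:
            report.add("error", loc,
                       f"{var.arity} component tags for "
                       f"{rxn.GetNumReactantTemplates()} reagent templates")
        for tag in var.component_tags:
            used_tags.add(tag)
            hits = [s for s in defn.synthons
                    if not s.is_precursor and tag in s.reaction_tags]
            if not hits:
                report.add("error", loc, f"unresolved tag {tag!r}")
            elif len(hits) > 1:
                report.add("error", loc,
                           f"tag {tag!r} is ambiguous across "
                           f"{[s.synthon_id for s in hits]}")

    for syn in defn.synthons:
        if not any(tag in used_tags for tag in syn.reaction_tags):
            report.add("warning", f"synthon {syn.synthon_id}",
                       "never referenced by any variant")
    return report


# ---------------------------------------------------------------------------
# built-in library


_BUILTINS = (
    ("beta_keto_imides", "beta-keto-imides", "BETA_KETO_IMIDES"),
    ("amino_thiatriazoles", "5-amino-thiatriazoles", "AMINO_THIATRIAZOLES"),
    ("amino_tetrazoles", "5-amino-tetrazoles", "AMINO_TETRAZOLES"),
    ("truce_smiles", "Truce-Smiles rearrangement", "TRUCE_SMILES"),
    ("cycloaddition_2_2", "[2+2]-cycloaddition", "CYCLOADDITION_2_2"),
    ("cycloaddition_4_2", "[4+2]-cycloaddition", "CYCLOADDITION_4_2"),
)


def _read_data(name: str) -> str:
    return (resources.files("rxnenum.data") / name).read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def _builtin_tuple() -> tuple[ReactionDefinition, ...]:
    defs = []
    for reaction_id, display_name, stem in _BUILTINS:
        defs.append(load_definition(
            reaction_id, display_name,
            _read_data(f"{stem}_Reagents.txt"),
            _read_data(f"{stem}_Reactions.txt"),
        ))
    return tuple(defs)


def builtin_library() -> list[ReactionDefinition]:
    """The six packaged reaction definitions, in fixed order."""
    return list(_builtin_tuple())


def builtin(reaction_id: str) -> ReactionDefinition:
    for defn in _builtin_tuple():
        if defn.reaction_id == reaction_id:
            return defn
    raise KeyError(reaction_id)
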