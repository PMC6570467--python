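"""Metabolic-gene selection from Enzyme Commission annotations.

A gene counts as metabolic when at least one of its EC numbers describes a
small-molecule transformation, i.e. does not match any exclusion prefix for
enzymes acting on proteins or nucleic acids (kinases of proteins, peptidases,
polymerases, tRNA ligases, topoisomerases, ...). The default exclusion list
ships as an editable YAML file so a curated list can replace it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_EC_RE = re.compile(r"^[1-7]\.(\d+|-)\.(\d+|-)\.(\d+|-)$")
_EC_PREFIX_RE = re.compile(r"^[1-7](\.\d+){0,3}$")


@dataclass(frozen=True)
class ExclusionRule:
    prefix: str
    reason: str

    def __post_init__(self) -> None:
        if not _EC_PREFIX_RE.match(self.prefix):
            raise ValueError(f"invalid EC prefix {self.prefix!r}")

    def matches(self, ec: str) -> bool:
        fields = ec.split(".")
        pref = self.prefix.split(".")
        return fields[: len(pref)] == pref


def is_valid_ec(ec: str) -> bool:
    if not _EC_RE.match(ec):
        return False
    return all(f == "-" or int(f) > 0 for f in ec.split("."))


def default_rules() -> list[ExclusionRule]:
    """Exclusion rules for enzymes whose substrates are proteins or genes."""
    text = resources.files("metaprior").joinpath(
        "data/ec_exclusions.yaml").read_text()
    return load_rules_yaml_text(text)


def load_rules_yaml_text(text: str) -> list[ExclusionRule]:
    raw = yaml.safe_load(text) or []
    return [ExclusionRule(str(r["prefix"]), str(r.get("reason", ""))) for r in raw]


def load_rules(path: str | Path) -> list[ExclusionRule]:
    return load_rules_yaml_text(Path(path).read_text())


def parse_ec_map(path: str | Path) -> tuple[dict[str, set[str]], list[str]]:
    """Parse a two-column (gene, EC) TSV into gene -> set of ECs.

    Malformed rows are rejected and reported with their line numbers; an
    unreadable file raises. Returns (annotation, error report lines).
    """
    ann: dict[str, set[str]] = {}
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and len(parts) >= 2 and parts[1].lower() in ("ec", "ec_number"):
                continue  # header
            if len(parts) < 2 or not is_valid_ec(parts[1]):
                errors.append(f"line {lineno}: malformed row {line!r}")
                continue
            ann.setdefault(parts[0], set()).add(parts[1])
    if not ann:
        logger.warning("EC map %s yielded no annotations", path)
    return ann, errors


def annotation_from_frame(ec_map: pd.DataFrame) -> dict[str, set[str]]:
    """Build the gene -> ECs annotation from a (gene, ec) DataFrame."""
    ann: dict[str, set[str]] = {}
    for gene, ec in zip(ec_map["gene"], ec_map["ec"]):
        if not is_valid_ec(ec):
            raise ValueError(f"invalid EC {ec!r} for gene {gene}")
        ann.setdefault(gene, set()).add(ec)
    return ann


def is_small_molecule_ec(ec: str, rules: list[ExclusionRule] | None = None) -> bool:
    """True unless the EC matches an exclusion prefix (protein/gene substrate)."""
    if not is_valid_ec(ec):
        raise ValueError(f"invalid EC number {ec!r}")
    if rules is None:
        rules = default_rules()
    return not any(rule.matches(ec) for rule in rules)


def select_metabolic_genes(ann: dict[str, set[str]],
                           rules: list[ExclusionRule] | None = None
                           ) -> set[str]:
    """Genes with at least one small-molecule EC number.

    A gene carrying both a retained and an excluded EC is retained (the
    inclusive reading: it does transform small molecules).
    """
    if rules is None:
        rules = default_rules()
    return {g for g, ecs in ann.items()
            if any(is_small_molecule_ec(ec, rules) for ec in ecs)}


def write_gene_set(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in sorted(genes)))


def read_gene_set(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}
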