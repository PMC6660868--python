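"""Domain types, reference-table machinery and validation.

The scoring model rates regulated establishments on ordinal risk variables
(scores 1..5, 5 = highest risk).  Variables are either *transversal*
(common to every product line) or *propia* (specific to one product line),
each with a weight; product risks carry Severity / Occurrence / Affectation
scores.  This module defines the containers, the reference-table lookup
(qualitative condition -> ordinal score), config (de)serialization and the
registry file formats shared by the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

__all__ = [
    "PRODUCT_LINES",
    "Band",
    "ComponentScores",
    "ConfigError",
    "EstablishmentRecord",
    "ModelConfig",
    "ReferenceTable",
    "SOARisk",
    "ScoreLookupError",
    "ValidationFinding",
    "VariableDefinition",
    "WEIGHT_SUM_TOLERANCE",
    "config_from_yaml",
    "config_to_yaml",
    "load_config",
    "lookup_score",
    "read_registry",
    "round_half_up",
    "save_config",
    "validate_config",
    "validate_record",
    "write_registry",
]

#: Product lines the regulator oversees.  ``other`` is an escape hatch for
#: lines not in the canonical list.
PRODUCT_LINES = (
    "alimentos",
    "frigoríficos",
    "cosméticos",
    "medicamentos",
    "dispositivos_médicos",
    "bancos_de_tejidos",
    "bancos_de_sangre",
    "other",
)

#: Published weight tables are percentages rounded to two decimals, so group
#: sums can miss 1 by rounding error (e.g. 99.99%).  Sums within this
#: tolerance are renormalized; larger deviations are fatal.
WEIGHT_SUM_TOLERANCE = 0.005

VALID_SCORES = frozenset({1, 2, 3, 4, 5})


class Band(str, Enum):
    """Risk band of an aggregated index value (most to least urgent)."""

    muy_alto = "muy_alto"
    alto = "alto"
    moderado = "moderado"
    bajo = "bajo"


class ConfigError(ValueError):
    """Fatal problem in a model configuration or registry file."""


class ScoreLookupError(KeyError):
    """A condition label missing from a reference table with no default."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how report figures are printed.

    Internal arithmetic is kept at full float precision; this is applied only
    at display/report time.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceTable:
    """Ordered mapping of qualitative conditions to ordinal risk scores.

    Parameters
    ----------
    entries
        Ordered ``(condition_label, score)`` pairs; scores in 1..5 and labels
        unique within the table.
    default_score
        Score returned for labels not listed; ``None`` makes unknown labels
        an error.
    """

    entries: tuple[tuple[str, int], ...]
    default_score: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple((str(c), int(s)) for c, s in self.entries))
        labels = [c for c, _ in self.entries]
        if len(labels) != len(set(labels)):
            raise ConfigError("reference table has duplicate condition labels")
        for label, score in self.entries:
            if score not in VALID_SCORES:
                raise ConfigError(f"reference table score {score!r} for {label!r} outside 1..5")
        if self.default_score is not None and self.default_score not in VALID_SCORES:
            raise ConfigError(f"default_score {self.default_score!r} outside 1..5")


@dataclass(frozen=True)
class VariableDefinition:
    """One ordinal risk variable with its reference table and weight."""

    id: str
    name: str
    scope: str  # "transversal" | "propia"
    product_line: str  # a product-line tag, or "all"
    weight: float
    reference_table: ReferenceTable

    def __post_init__(self) -> None:
        if self.scope not in ("transversal", "propia"):
            raise ConfigError(f"variable {self.id}: unknown scope {self.scope!r}")
        if self.scope == "transversal" and self.product_line != "all":
            raise ConfigError(
                f"variable {self.id}: transversal variables apply to all product "
                f"lines, got product_line={self.product_line!r}"
            )
        if self.weight < 0:
            raise ConfigError(f"variable {self.id}: negative weight {self.weight}")


@dataclass(frozen=True)
class SOARisk:
    """Severity / Occurrence / Affectation scores for one product risk.

    Severity reflects intrinsic harm potential of the product class,
    occurrence the observed failure frequency, affectation the size and
    vulnerability of the exposed population; each on the 1..5 scale.
    """

    risk_id: str
    severity: int
    occurrence: int
    affectation: int

    def __post_init__(self) -> None:
        for name in ("severity", "occurrence", "affectation"):
            v = getattr(self, name)
            if v not in VALID_SCORES:
                raise ConfigError(f"risk {self.risk_id}: {name}={v!r} outside 1..5")


@dataclass(frozen=True)
class EstablishmentRecord:
    """One regulated establishment's pre-coded risk profile inputs."""

    id: str
    product_line: str
    transversal_scores: Mapping[str, int]
    propia_scores: Mapping[str, int]
    risks: tuple[SOARisk, ...] = ()
    incomplete: bool = False  # True permits an empty risk list

    def __post_init__(self) -> None:
        object.__setattr__(self, "transversal_scores", dict(self.transversal_scores))
        object.__setattr__(self, "propia_scores", dict(self.propia_scores))
        object.__setattr__(self, "risks", tuple(self.risks))


@dataclass(frozen=True)
class ModelConfig:
    """Full model configuration: variables, component betas and options."""

    variables: tuple[VariableDefinition, ...]
    betas: tuple[float, float, float]  # weights of (VT, VP, SOA)
    soa_aggregation: str = "max"  # "max" | "weighted_mean"
    band_edges: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    percentile_method: str = "linear interpolation between closest ranks"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if self.soa_aggregation not in ("max", "weighted_mean"):
            raise ConfigError(f"unknown soa_aggregation {self.soa_aggregation!r}")

    # -- convenience views -------------------------------------------------

    def variable(self, var_id: str) -> VariableDefinition:
        for v in self.variables:
            if v.id == var_id:
                return v
        raise KeyError(var_id)

    def transversal_variables(self) -> tuple[VariableDefinition, ...]:
        return tuple(v for v in self.variables if v.scope == "transversal")

    def propia_variables(self, product_line: str) -> tuple[VariableDefinition, ...]:
        return tuple(
            v
            for v in self.variables
            if v.scope == "propia" and v.product_line in (product_line, "all")
        )


@dataclass(frozen=True)
class ComponentScores:
    """Scored risk profile of one establishment: the (VT, VP, SOA) component
    triple, the aggregated index IRA = b1*VT + b2*VP + b3*SOA and its band."""

    establishment_id: str
    vt: float
    vp: float
    soa: float
    ira: float
    band: Band
    product_line: str = "other"


@dataclass(frozen=True)
class ValidationFinding:
    """One validation message; ``fatal`` findings abort a run."""

    fatal: bool
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        level = "FATAL" if self.fatal else "WARN"
        return f"[{level}] {self.subject}: {self.message}"


# ---------------------------------------------------------------------------
# Reference-table lookup and validation
# ---------------------------------------------------------------------------


def lookup_score(table: ReferenceTable, condition_label: str, *, variable_id: str = "?") -> int:
    """Map a qualitative condition to its ordinal score via the table.

    Falls back to ``default_score`` for unlisted labels; raises
    :class:`ScoreLookupError` naming the variable and label when no default
    is defined.
    """
    for label, score in table.entries:
        if label == condition_label:
            return score
    if table.default_score is not None:
        return table.default_score
    raise ScoreLookupError(
        f"variable {variable_id}: condition {condition_label!r} not in reference "
        f"table and no default score is defined"
    )


def _weight_groups(
    variables: Sequence[VariableDefinition],
) -> dict[tuple[str, str], list[VariableDefinition]]:
    groups: dict[tuple[str, str], list[VariableDefinition]] = {}
    for v in variables:
        groups.setdefault((v.scope, v.product_line), []).append(v)
    return groups


def validate_config(config: ModelConfig) -> tuple[ModelConfig, list[ValidationFinding]]:
    """Check config invariants; renormalize weights/betas within tolerance.

    Returns the (possibly renormalized) config and a list of findings.  The
    finding list is empty iff all invariants hold; weight-group sums within
    ``WEIGHT_SUM_TOLERANCE`` of 1 are silently renormalized to sum exactly 1
    (published tables carry rounded percentages), larger deviations produce
    a fatal finding.
    """
    findings: list[ValidationFinding] = []

    ids = [v.id for v in config.variables]
    for dup in {i for i in ids if ids.count(i) > 1}:
        findings.append(ValidationFinding(True, dup, "duplicate variable id"))

    beta_sum = sum(config.betas)
    if any(b < 0 for b in config.betas):
        findings.append(ValidationFinding(True, "betas", f"negative beta in {config.betas}"))
    elif abs(beta_sum - 1.0) > WEIGHT_SUM_TOLERANCE + 1e-12:
        findings.append(
            ValidationFinding(True, "betas", f"betas sum {beta_sum:.6g} > tolerance")
        )

    new_vars: list[VariableDefinition] = list(config.variables)
    for (scope, line), group in _weight_groups(config.variables).items():
        s = sum(v.weight for v in group)
        # epsilon keeps a deviation of exactly the tolerance acceptable
        if abs(s - 1.0) > WEIGHT_SUM_TOLERANCE + 1e-12:
            findings.append(
                ValidationFinding(
                    True,
                    f"{scope}/{line}",
                    f"weights sum {s:.6g} > tolerance",
                )
            )
        elif s > 0 and s != 1.0:
            for i, v in enumerate(new_vars):
                if v in group:
                    new_vars[i] = replace(v, weight=v.weight / s)

    if any(f.fatal for f in findings):
        return config, findings

    if abs(beta_sum - 1.0) > 0:
        config = replace(config, betas=tuple(b / beta_sum for b in config.betas))
    config = replace(config, variables=tuple(new_vars))
    return config, findings


def validate_record(record: EstablishmentRecord, config: ModelConfig) -> list[ValidationFinding]:
    """Check one registry record against the configuration."""
    findings: list[ValidationFinding] = []
    known = {v.id: v for v in config.variables}
    for kind, scores in (
        ("transversal", record.transversal_scores),
        ("propia", record.propia_scores),
    ):
        for var_id, score in scores.items():
            if var_id not in known:
                findings.append(
                    ValidationFinding(True, record.id, f"unknown variable id {var_id!r}")
                )
                continue
            v = known[var_id]
            if v.scope != kind:
                findings.append(
                    ValidationFinding(
                        True, record.id, f"variable {var_id} has scope {v.scope}, used as {kind}"
                    )
                )
            if v.scope == "propia" and v.product_line not in (record.product_line, "all"):
                findings.append(
                    ValidationFinding(
                        True,
                        record.id,
                        f"variable {var_id} belongs to line {v.product_line}, "
                        f"record is {record.product_line}",
                    )
                )
            if score not in VALID_SCORES:
                findings.append(
                    ValidationFinding(True, record.id, f"score {score!r} for {var_id} outside 1..5")
                )
    if not record.risks and not record.incomplete:
        findings.append(
            ValidationFinding(True, record.id, "no assessed risks and record not flagged incomplete")
        )
    return findings


# ---------------------------------------------------------------------------
# Config (de)serialization — YAML key-value tree
# ---------------------------------------------------------------------------


def _table_to_obj(t: ReferenceTable) -> dict:
    obj: dict = {"entries": [{"condition": c, "score": s} for c, s in t.entries]}
    if t.default_score is not None:
        obj["default_score"] = t.default_score
    return obj


def config_to_yaml(config: ModelConfig) -> str:
    """Serialize a ModelConfig to a YAML document (round-trip safe)."""
    obj = {
        "betas": {"vt": config.betas[0], "vp": config.betas[1], "soa": config.betas[2]},
        "soa_aggregation": config.soa_aggregation,
        "variables": [
            {
                "id": v.id,
                "name": v.name,
                "scope": v.scope,
                "product_line": v.product_line,
                "weight": v.weight,
                "reference_table": _table_to_obj(v.reference_table),
            }
            for v in config.variables
        ],
    }
    return yaml.safe_dump(obj, allow_unicode=True, sort_keys=False)


def config_from_yaml(text: str) -> ModelConfig:
    """Parse a YAML model configuration; raises ConfigError on malformed input."""
    try:
        obj = yaml.safe_load(text)
    except yaml.YAMLError as e:  # pragma: no cover - passthrough
        raise ConfigError(f"malformed YAML: {e}") from e
    if not isinstance(obj, dict):
        raise ConfigError("config root must be a mapping")
    try:
        betas_obj = obj["betas"]
        betas = (float(betas_obj["vt"]), float(betas_obj["vp"]), float(betas_obj["soa"]))
        variables = []
        for vo in obj["variables"]:
            to = vo["reference_table"]
            table = ReferenceTable(
                entries=tuple((e["condition"], int(e["score"])) for e in to.get("entries", [])),
                default_score=to.get("default_score"),
            )
            variables.append(
                VariableDefinition(
                    id=str(vo["id"]),
                    name=str(vo.get("name", vo["id"])),
                    scope=str(vo["scope"]),
                    product_line=str(vo.get("product_line", "all")),
                    weight=float(vo["weight"]),
                    reference_table=table,
                )
            )
    except (KeyError, TypeError) as e:
        raise ConfigError(f"config missing required field: {e}") from e
    return ModelConfig(
        variables=tuple(variables),
        betas=betas,
        soa_aggregation=obj.get("soa_aggregation", "max"),
    )


def load_config(path: Union[str, Path]) -> ModelConfig:
    return config_from_yaml(Path(path).read_text(encoding="utf-8"))


def save_config(config: ModelConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(config_to_yaml(config), encoding="utf-8")


# ---------------------------------------------------------------------------
# Registry I/O — delimited text
# ---------------------------------------------------------------------------
#
# Registry: one CSV row per establishment, wide variable-score columns
# (blank where a variable does not apply to the record's product line), plus
# a long-form companion CSV of product risks
# (establishment_id, risk_id, severity, occurrence, affectation).


def write_registry(
    records: Iterable[EstablishmentRecord],
    registry_path: Union[str, Path],
    risks_path: Union[str, Path],
    config: ModelConfig,
) -> None:
    """Write records to the wide registry CSV + long risks CSV pair."""
    records = list(records)
    var_ids = [v.id for v in config.variables]
    rows = []
    for r in records:
        row: dict = {"id": r.id, "product_line": r.product_line, "incomplete": int(r.incomplete)}
        merged = {**r.transversal_scores, **r.propia_scores}
        for vid in var_ids:
            row[vid] = merged.get(vid, "")
        rows.append(row)
    pd.DataFrame(rows, columns=["id", "product_line", "incomplete", *var_ids]).to_csv(
        registry_path, index=False, encoding="utf-8"
    )

    risk_rows = [
        {
            "establishment_id": r.id,
            "risk_id": k.risk_id,
            "severity": k.severity,
            "occurrence": k.occurrence,
            "affectation": k.affectation,
        }
        for r in records
        for k in r.risks
    ]
    pd.DataFrame(
        risk_rows,
        columns=["establishment_id", "risk_id", "severity", "occurrence", "affectation"],
    ).to_csv(risks_path, index=False, encoding="utf-8")


def read_registry(
    registry_path: Union[str, Path],
    risks_path: Union[str, Path],
    config: ModelConfig,
) -> list[EstablishmentRecord]:
    """Read the registry/risks CSV pair into establishment records.

    Raises :class:`ConfigError` with the file, row and field on malformed
    content.  Score columns unknown to the config are rejected.
    """
    reg = pd.read_csv(registry_path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("id", "product_line"):
        if col not in reg.columns:
            raise ConfigError(f"{registry_path}: missing required column {col!r}")
    known = {v.id: v for v in config.variables}
    score_cols = [c for c in reg.columns if c not in ("id", "product_line", "incomplete")]
    for c in score_cols:
        if c not in known:
            raise ConfigError(f"{registry_path}: unknown variable id {c!r} in header")

    risks_df = pd.read_csv(risks_path, dtype=str, keep_default_na=False, encoding="utf-8")
    needed = {"establishment_id", "risk_id", "severity", "occurrence", "affectation"}
    if not risks_df.empty and not needed.issubset(risks_df.columns):
        raise ConfigError(f"{risks_path}: missing columns {sorted(needed - set(risks_df.columns))}")
    risks_by_est: dict[str, list[SOARisk]] = {}
    for i, row in risks_df.iterrows():
        try:
            risk = SOARisk(
                risk_id=row["risk_id"],
                severity=int(row["severity"]),
                occurrence=int(row["occurrence"]),
                affectation=int(row["affectation"]),
            )
        except (ValueError, ConfigError) as e:
            raise ConfigError(f"{risks_path}: row {i + 2}: {e}") from e
        risks_by_est.setdefault(row["establishment_id"], []).append(risk)

    records: list[EstablishmentRecord] = []
    for i, row in reg.iterrows():
        tv: dict[str, int] = {}
        pv: dict[str, int] = {}
        for c in score_cols:
            raw = row[c].strip()
            if raw == "":
                continue
            try:
                score = int(float(raw))
            except ValueError as e:
                raise ConfigError(
                    f"{registry_path}: row {i + 2}, field {c!r}: not an integer score ({raw!r})"
                ) from e
            (tv if known[c].scope == "transversal" else pv)[c] = score
        raw_inc = row["incomplete"].strip() if "incomplete" in reg.columns else "0"
        incomplete = raw_inc not in ("", "0")
        records.append(
            EstablishmentRecord(
                id=row["id"],
                product_line=row["product_line"],
                transversal_scores=tv,
                propia_scores=pv,
                risks=tuple(risks_by_est.get(row["id"], ())),
                incomplete=incomplete,
            )
        )
    return records
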