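"""Core scoring math: VT/VP component scores, SOA standardization, the
aggregated risk index IRA and its band.

Per establishment *i* the model computes

    IRA_i = b1 * VT_i + b2 * VP_i + b3 * SOA_i,      b1 + b2 + b3 = 1,

where VT_i and VP_i are weighted means of the transversal / product-line
ordinal variable scores, and SOA_i aggregates per-product-risk scores
(S*O*A)^(1/3) — the cube root maps the 1..125 product back onto the 1..5
scale.  All component scores and the IRA therefore live in [1, 5].
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

from .domain import (
    Band,
    ComponentScores,
    EstablishmentRecord,
    ModelConfig,
    SOARisk,
    validate_config,
)

__all__ = [
    "MissingScoreWarning",
    "ScoringError",
    "classify_band",
    "ira",
    "score_component",
    "score_establishment",
    "score_portfolio",
    "soa_component",
    "soa_score",
]


class ScoringError(ValueError):
    """A record cannot be scored (empty components, invalid inputs)."""


class MissingScoreWarning(UserWarning):
    """Some configured variables were unscored; weights were renormalized."""


def score_component(
    scores: Mapping[str, int], weights: Mapping[str, float]
) -> float:
    """Weighted mean of ordinal variable scores for one component.

    Weights are renormalized over the variables actually present in
    ``scores``; a :class:`MissingScoreWarning` is emitted when configured
    variables are missing (the record is scored on the rest rather than
    dropped).
    """
    if not scores:
        raise ScoringError("no scorable variables")
    missing = [k for k in weights if k not in scores]
    unknown = [k for k in scores if k not in weights]
    if unknown:
        raise ScoringError(f"scores for unweighted variables: {unknown}")
    w = {k: weights[k] for k in scores}
    total = sum(w.values())
    if total <= 0:
        raise ScoringError("weights over scored variables sum to zero")
    if missing:
        warnings.warn(
            f"missing scores for {missing}; renormalizing remaining weights",
            MissingScoreWarning,
            stacklevel=2,
        )
    return sum(weights[k] * scores[k] for k in scores) / total


def soa_score(risk: SOARisk) -> float:
    """Standardized score of one product risk: cube root of S*O*A.

    Severity, occurrence and affectation are each 1..5; their product spans
    1..125 and the cube root standardizes it back to the 1..5 risk scale.
    """
    return float(risk.severity * risk.occurrence * risk.affectation) ** (1.0 / 3.0)


def soa_component(risks: Sequence[SOARisk], mode: str = "max") -> float:
    """Aggregate per-risk standardized scores into one SOA component.

    ``max`` (default) takes the worst product risk — the conservative
    choice; ``weighted_mean`` averages (currently equal weights per risk).
    """
    if not risks:
        raise ScoringError("establishment has no assessed risks")
    per_risk = [soa_score(r) for r in risks]
    if mode == "max":
        return max(per_risk)
    if mode == "weighted_mean":
        return sum(per_risk) / len(per_risk)
    raise ScoringError(f"unknown SOA aggregation mode {mode!r}")


def ira(vt: float, vp: float, soa: float, betas: Sequence[float]) -> float:
    """Aggregated risk index: beta-weighted combination of the components."""
    b1, b2, b3 = betas
    if abs((b1 + b2 + b3) - 1.0) > 1e-9:
        raise ScoringError(f"betas {betas!r} not normalized to sum 1")
    return b1 * vt + b2 * vp + b3 * soa


def classify_band(value: float) -> Band:
    """Band an IRA value: bajo [1,2), moderado [2,3), alto [3,4), muy_alto [4,5].

    Intervals are half-open with the top closed at 5, so a boundary value
    escalates to the more protective band.
    """
    if not (1.0 <= value <= 5.0):
        raise ScoringError(f"IRA {value!r} outside the [1, 5] scale")
    if value >= 4.0:
        return Band.muy_alto
    if value >= 3.0:
        return Band.alto
    if value >= 2.0:
        return Band.moderado
    return Band.bajo


def score_establishment(record: EstablishmentRecord, config: ModelConfig) -> ComponentScores:
    """Compute the full (VT, VP, SOA, IRA, band) profile for one record.

    Deterministic composition of the component operations; errors from the
    sub-operations are re-raised annotated with the establishment id.
    """
    vt_weights = {v.id: v.weight for v in config.transversal_variables()}
    vp_weights = {v.id: v.weight for v in config.propia_variables(record.product_line)}
    try:
        vt = score_component(record.transversal_scores, vt_weights)
        vp = score_component(record.propia_scores, vp_weights)
        soa = soa_component(record.risks, mode=config.soa_aggregation)
        value = ira(vt, vp, soa, config.betas)
    except ScoringError as e:
        raise ScoringError(f"establishment {record.id}: {e}") from e
    return ComponentScores(
        establishment_id=record.id,
        vt=vt,
        vp=vp,
        soa=soa,
        ira=value,
        band=classify_band(value),
        product_line=record.product_line,
    )


def score_portfolio(
    records: Iterable[EstablishmentRecord], config: ModelConfig
) -> tuple[list[ComponentScores], list[str]]:
    """Batch scoring entry point.

    Validates and renormalizes the config once, then scores every record,
    collecting per-record warnings (missing variables) into a log list.
    Fatal config findings raise immediately.
    """
    config, findings = validate_config(config)
    fatal = [f for f in findings if f.fatal]
    if fatal:
        raise ScoringError("; ".join(str(f) for f in fatal))
    profiles: list[ComponentScores] = []
    log: list[str] = []
    for record in records:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", MissingScoreWarning)
            profiles.append(score_establishment(record, config))
        log.extend(f"{record.id}: {w.message}" for w in caught)
    return profiles, log
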