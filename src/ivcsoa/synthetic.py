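"""Synthetic portfolios with known latent structure, plus the canonical
worked-example fixture.

No public registry of real establishment scores exists, so every stage of
the pipeline — scoring, weight estimation, aggregation — is exercised on
generated data with controlled ground truth: each establishment carries a
latent risk factor F ~ N(0, 1); every ordinal variable score is a
discretization of ``loading * F + sqrt(1 - loading^2) * noise`` at standard
normal quintile cut-points, so marginal category frequencies are uniform
and a variable's Spearman correlation with F rises monotonically with its
loading.  S/O/A scores come from the same discretization with their own
loading, so the SOA component co-moves with VT/VP as the model assumes.

The generator emulates cross-sectional dependence through a single common
factor only; it does not reproduce the skewed marginals, serial updates or
line-specific base rates of a real inspection registry.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np
from scipy.stats import norm  # quintile cut-points

from .domain import (
    EstablishmentRecord,
    ModelConfig,
    ReferenceTable,
    SOARisk,
    VariableDefinition,
    config_from_yaml,
    read_registry,
    write_registry,
)

__all__ = [
    "QUINTILE_CUTS",
    "dairy_example",
    "discretize",
    "generate_portfolio",
    "synthetic_config",
    "write_portfolio_files",
]

#: Standard-normal quintile cut-points; a latent value is mapped to the
#: 1..5 score of the quintile it falls in.
QUINTILE_CUTS = norm.ppf([0.2, 0.4, 0.6, 0.8])


def discretize(latent: np.ndarray) -> np.ndarray:
    """Map latent values to ordinal 1..5 scores at the quintile cut-points."""
    return (np.searchsorted(QUINTILE_CUTS, latent) + 1).astype(int)


def _latent_scores(
    rng: np.random.Generator, F: np.ndarray, loading: float
) -> np.ndarray:
    if not 0.0 <= loading <= 1.0:
        raise ValueError(f"loading {loading!r} outside [0, 1]")
    noise = rng.standard_normal(F.shape)
    return discretize(loading * F + np.sqrt(1.0 - loading**2) * noise)


def generate_portfolio(
    n: int,
    config: ModelConfig,
    latent_loading: Mapping[str, float],
    seed: int,
    *,
    soa_loading: float = 0.6,
    n_risks: int = 1,
    product_line: str = "alimentos",
) -> list[EstablishmentRecord]:
    """Generate ``n`` establishment records driven by a common risk factor.

    ``latent_loading`` maps each config variable id to its loading on the
    latent factor (0 = pure noise, 1 = the factor itself).  S, O and A of
    each of ``n_risks`` product risks use ``soa_loading``.  Bit-reproducible
    for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal(n)
    tv_vars = config.transversal_variables()
    vp_vars = config.propia_variables(product_line)
    scores: dict[str, np.ndarray] = {}
    for v in (*tv_vars, *vp_vars):
        scores[v.id] = _latent_scores(rng, F, float(latent_loading.get(v.id, 0.0)))

    # S/O/A per risk: same latent-shift construction, own noise per score
    soa_draws = np.stack(
        [_latent_scores(rng, F, soa_loading) for _ in range(3 * n_risks)], axis=1
    ).reshape(n, n_risks, 3)

    records: list[EstablishmentRecord] = []
    for i in range(n):
        risks = tuple(
            SOARisk(
                risk_id=f"R{k + 1}",
                severity=int(soa_draws[i, k, 0]),
                occurrence=int(soa_draws[i, k, 1]),
                affectation=int(soa_draws[i, k, 2]),
            )
            for k in range(n_risks)
        )
        records.append(
            EstablishmentRecord(
                id=f"est-{i + 1:05d}",
                product_line=product_line,
                transversal_scores={v.id: int(scores[v.id][i]) for v in tv_vars},
                propia_scores={v.id: int(scores[v.id][i]) for v in vp_vars},
                risks=risks,
            )
        )
    return records


def synthetic_config(
    n_transversal: int = 7,
    n_propia: int = 3,
    product_line: str = "alimentos",
    betas: tuple[float, float, float] = (0.45, 0.25, 0.30),
) -> ModelConfig:
    """A minimal config with equal weights and pass-through reference tables,
    for simulations where only the numeric machinery matters."""
    table = ReferenceTable(entries=(), default_score=3)
    variables = [
        VariableDefinition(
            id=f"VT{i + 1}",
            name=f"transversal variable {i + 1}",
            scope="transversal",
            product_line="all",
            weight=1.0 / n_transversal,
            reference_table=table,
        )
        for i in range(n_transversal)
    ] + [
        VariableDefinition(
            id=f"VP{i + 1}",
            name=f"{product_line} variable {i + 1}",
            scope="propia",
            product_line=product_line,
            weight=1.0 / n_propia,
            reference_table=table,
        )
        for i in range(n_propia)
    ]
    return ModelConfig(variables=tuple(variables), betas=betas)


def write_portfolio_files(
    records: list[EstablishmentRecord],
    config: ModelConfig,
    out_dir: Union[str, Path],
    *,
    seed: int | None = None,
    params: Mapping | None = None,
) -> tuple[Path, Path]:
    """Write a generated portfolio in the registry format the scorer reads,
    with a JSON sidecar recording the seed and generator parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry_path = out / "registry.csv"
    risks_path = out / "risks.csv"
    write_registry(records, registry_path, risks_path, config)
    meta = {"n": len(records), "seed": seed, "params": dict(params or {})}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return registry_path, risks_path


# ---------------------------------------------------------------------------
# Worked-example fixture (dairy establishment)
# ---------------------------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("ivcsoa.data").joinpath(name).read_text(encoding="utf-8")


def dairy_example() -> tuple[EstablishmentRecord, ModelConfig]:
    """The published dairy-products worked example.

    A dairy establishment scored on the seven transversal variables
    (activity complexity 4, standards compliance 3, time since last visit 3,
    sanitary measures 2, complaint history 3, sanitary registrations 2,
    technical responsible 5), three food-line variables (establishment type
    5, foodborne-disease reports 4, HACCP certification 3) and one product
    risk (microbiological quality failure: S=5, O=3, A=5), with component
    betas (0.45, 0.25, 0.30).  Scoring it yields VT 3.04, VP 4.27, SOA 4.22
    and IRA 3.70 (band alto) at two-decimal display rounding.
    """
    config = config_from_yaml(_data_text("dairy_config.yaml"))
    import tempfile

    with tempfile.TemporaryDirectory() as td:
        reg = Path(td) / "registry.csv"
        rk = Path(td) / "risks.csv"
        reg.write_text(_data_text("dairy_registry.csv"), encoding="utf-8")
        rk.write_text(_data_text("dairy_risks.csv"), encoding="utf-8")
        records = read_registry(reg, rk, config)
    assert len(records) == 1
    return records[0], config
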