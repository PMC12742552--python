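"""Reading and writing dose-toxicity tables, run configuration, and audit headers.

The canonical on-disk format is a single long CSV with header columns
``compound, population, dose, n, dlt`` (population in {source, target};
``s``/``t`` accepted and normalized).  Reference doses are per-compound
configuration, not table columns, to avoid repetition and ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .blrm import DoseGrid, TrialOutcome
from .similarity import ArmData, CompoundDataset

__all__ = [
    "RunConfig",
    "read_compound_table",
    "write_compound_table",
    "read_trial_table",
    "write_trial_table",
    "resolve_reference_dose",
]

REQUIRED_COLUMNS = ("compound", "population", "dose", "n", "dlt")
_POPULATION_ALIASES = {"source": "source", "s": "source", "target": "target", "t": "target"}


@dataclass
class RunConfig:
    """Settings serialized into every results file for reproducibility."""

    seed: int = 0
    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    similarity_warmup: int = 1000
    theta: float = 0.30
    no_skip: bool = True
    transform_base: float = 0.01
    model: str = "exnex"
    reference_doses: dict[str, float] = field(default_factory=dict)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return RunConfig(**data)

    def audit_header(self) -> str:
        """Comment block embedded at the top of result files."""
        from . import __version__

        payload = asdict(self)
        payload["doseborrow_version"] = __version__
        return "\n".join(f"# {line}" for line in json.dumps(payload).splitlines())


def _normalize_population(value, row: int) -> str:
    key = str(value).strip().lower()
    if key not in _POPULATION_ALIASES:
        raise ValueError(
            f"row {row}: unknown population label {value!r} "
            "(expected 'source'/'target')"
        )
    return _POPULATION_ALIASES[key]


def read_compound_table(
    path: Union[str, Path],
    reference_doses: Mapping[str, float],
) -> list[CompoundDataset]:
    """Read a multi-compound long-format CSV into CompoundDataset objects.

    ``reference_doses`` maps compound id to its reference dose; a missing
    entry is an error.  Validation failures name the offending table row
    (1-based, excluding the header).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    df = df.copy()
    df["_row"] = np.arange(1, len(df) + 1)
    df["population"] = [
        _normalize_population(v, r) for v, r in zip(df["population"], df["_row"])
    ]
    for _, rec in df.iterrows():
        row = int(rec["_row"])
        if rec["dose"] <= 0:
            raise ValueError(f"row {row}: dose must be positive")
        if rec["n"] < 0 or rec["dlt"] < 0:
            raise ValueError(f"row {row}: counts must be non-negative")
        if rec["dlt"] > rec["n"]:
            raise ValueError(
                f"row {row}: dlt ({rec['dlt']}) exceeds n ({rec['n']}) "
                f"for compound {rec['compound']!r}"
            )

    datasets = []
    for compound, group in df.groupby("compound", sort=False):
        compound = str(compound)
        if compound not in reference_doses:
            raise ValueError(f"missing reference dose for compound {compound!r}")
        ref = float(reference_doses[compound])
        arms = {}
        for pop in ("source", "target"):
            sub = group[group["population"] == pop].sort_values("dose")
            if sub.empty:
                raise ValueError(
                    f"compound {compound!r}: no rows for population {pop!r}"
                )
            if sub["dose"].duplicated().any():
                dup = sub[sub["dose"].duplicated()].iloc[0]
                raise ValueError(
                    f"row {int(dup['_row'])}: duplicate dose {dup['dose']} "
                    f"for compound {compound!r} population {pop!r}"
                )
            grid = DoseGrid(sub["dose"].tolist(), ref)
            outcome = TrialOutcome(sub["n"].tolist(), sub["dlt"].tolist())
            arms[pop] = ArmData(grid=grid, outcome=outcome)
        datasets.append(
            CompoundDataset(compound_id=compound, source=arms["source"], target=arms["target"])
        )
    return datasets


def write_compound_table(
    datasets: Sequence[CompoundDataset],
    path: Union[str, Path],
    config: Optional[RunConfig] = None,
) -> dict[str, float]:
    """Write datasets in the canonical long format; returns the reference-dose map.

    When a RunConfig is given, its audit header is embedded as comment lines
    before the CSV header (pandas skips them on read via ``comment='#'`` —
    `read_compound_table` tolerates them).
    """
    rows = []
    refs = {}
    for ds in datasets:
        refs[ds.compound_id] = ds.reference_dose
        for pop, arm in (("source", ds.source), ("target", ds.target)):
            for dose, n, y in zip(
                arm.grid.doses, arm.outcome.n_per_dose, arm.outcome.dlt_per_dose
            ):
                rows.append(
                    {"compound": ds.compound_id, "population": pop, "dose": dose, "n": n, "dlt": y}
                )
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.audit_header() + "\n")
        df.to_csv(fh, index=False)
    return refs


def write_trial_table(
    grid: DoseGrid,
    outcome: TrialOutcome,
    path: Union[str, Path],
    config: Optional[RunConfig] = None,
) -> None:
    """Write a single trial as a dose/n/dlt CSV (audit header optional)."""
    df = pd.DataFrame(
        {"dose": grid.doses, "n": outcome.n_per_dose, "dlt": outcome.dlt_per_dose}
    )
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.audit_header() + "\n")
        df.to_csv(fh, index=False)


def read_trial_table(
    path: Union[str, Path], reference_dose: float
) -> tuple[DoseGrid, TrialOutcome]:
    """Read a single-trial dose/n/dlt CSV back into a grid and outcome."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("dose", "n", "dlt") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    df = df.sort_values("dose")
    bad = df[df["dlt"] > df["n"]]
    if not bad.empty:
        raise ValueError(f"dlt exceeds n at dose {bad.iloc[0]['dose']}")
    return (
        DoseGrid(df["dose"].tolist(), reference_dose),
        TrialOutcome(df["n"].tolist(), df["dlt"].tolist()),
    )


def resolve_reference_dose(
    compound: CompoundDataset,
    mtd_source: Optional[int] = None,
    mtd_target: Optional[int] = None,
    override: Optional[float] = None,
) -> float:
    """Reference-dose selection rule for case-study-style data.

    Rule chain: an explicit override always wins; if both populations
    identified the same MTD dose value, use it; if only one population has an
    MTD, use that dose; if the MTDs differ, use the source-population MTD.
    ``mtd_source``/``mtd_target`` are 1-based dose levels into the respective
    population's grid.
    """
    if override is not None:
        if override <= 0:
            raise ValueError("reference dose override must be positive")
        return float(override)
    if mtd_source is None and mtd_target is None:
        raise ValueError(
            f"compound {compound.compound_id!r}: need an MTD in at least one "
            "population or an explicit reference dose"
        )
    dose_s = compound.source.grid.dose_value(mtd_source) if mtd_source else None
    dose_t = compound.target.grid.dose_value(mtd_target) if mtd_target else None
    if dose_s is None:
        return dose_t
    if dose_t is None or np.isclose(dose_s, dose_t):
        return dose_s
    return dose_s  # MTDs differ: the source-population MTD wins
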