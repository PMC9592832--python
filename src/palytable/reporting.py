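"""Rendering of burden results and run manifests.

Internally every number is kept at full precision; rounding and
billion/trillion scaling happen only here, at the rendering boundary.
Rendered tables mirror the standard burden layout: one row per income
stratum plus a Total row whose ratio columns are recomputed from the
summed numerators and denominators.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

from .economics import BurdenResult

__all__ = ["render_burden_table", "render_markdown", "RunManifest"]

_GROUP_LABELS = {
    "low": "Low-Income",
    "lower_middle": "Lower-Middle Income",
    "upper_middle": "Upper-Middle Income",
    "total": "Total",
}


def render_burden_table(
    strata: list[BurdenResult], total: BurdenResult
) -> pd.DataFrame:
    """Display table: cases in millions, losses in billions US$, GDP in
    trillions US$, loss/GDP in percent, rounded to 2 decimals."""
    rows = []
    for r in [*strata, total]:
        label = _GROUP_LABELS.get(r.scope_id, r.scope_id)
        rows.append(
            {
                "Economies": label,
                "Cases (millions)": round(r.cases / 1e6, 2),
                "Productivity losses (billions $)": round(r.gdp_lost / 1e9, 2),
                "GDP (trillions $)": round(r.gdp_total / 1e12, 2),
                "Productivity loss/GDP (%)": round(r.loss_gdp_pct, 2),
            }
        )
    return pd.DataFrame(rows)


def render_markdown(df: pd.DataFrame) -> str:
    """Markdown table of an already-rendered display frame."""
    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body]) + "\n"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every results file."""

    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path) -> None:
        self.inputs[os.path.basename(str(path))] = _sha256(path)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config": self.config,
                    "inputs": self.inputs,
                    "version": self.version,
                    "timestamp": self.timestamp,
                    "seed": self.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
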