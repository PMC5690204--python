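"""Measurement-uncertainty budgets: quadrature accumulation and expansion.

Components are relative standard uncertainties (percent, 1 SD), assumed
uncorrelated, combined in quadrature step by step; the combined standard
uncertainty is multiplied by a coverage factor k (k=2 ~ 95 % coverage) for
the expanded uncertainty. Values are stored at full precision and rounded
to two decimals only for display.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DomainError, InputError


def combine_quadrature(values: Iterable[float]) -> float:
    """Root-sum-of-squares of relative standard uncertainties (% at 1 SD)."""
    total = 0.0
    count = 0
    for v in values:
        if v < 0:
            raise DomainError(f"uncertainty components must be >= 0, got {v}")
        total += float(v) ** 2
        count += 1
    if count == 0:
        raise InputError("cannot combine an empty component list")
    return total ** 0.5


def expand(u: float, k: float) -> float:
    """Expanded uncertainty k*u for coverage factor k."""
    if u < 0:
        raise DomainError(f"standard uncertainty must be >= 0, got {u}")
    if k <= 0:
        raise DomainError(f"coverage factor must be > 0, got {k}")
    return k * u


@dataclass(frozen=True)
class UncertaintyComponent:
    label: str
    value_pct: float                  # relative standard uncertainty, % at 1 SD

    def __post_init__(self) -> None:
        if self.value_pct < 0:
            raise DomainError(
                f"component {self.label!r} has negative uncertainty")


@dataclass
class UncertaintyBudget:
    """Ordered uncertainty components with running quadrature totals."""

    components: list[UncertaintyComponent] = field(default_factory=list)
    coverage_factor: float = 2.0

    def add(self, label: str, value_pct: float) -> "UncertaintyBudget":
        self.components.append(UncertaintyComponent(label, value_pct))
        return self

    def cumulative(self) -> list[float]:
        """Combined standard uncertainty (1 SD, %) after each component."""
        if not self.components:
            raise InputError("budget has no components")
        out = []
        for i in range(len(self.components)):
            out.append(combine_quadrature(
                c.value_pct for c in self.components[: i + 1]))
        return out

    def combined(self) -> float:
        return self.cumulative()[-1]

    def expanded(self, k: float | None = None) -> float:
        return expand(self.combined(),
                      self.coverage_factor if k is None else k)

    # -- rendering / serialization ------------------------------------------

    def as_dataframe(self) -> pd.DataFrame:
        cum = self.cumulative()
        return pd.DataFrame({
            "source": [c.label for c in self.components],
            "for_step_1sd_pct": [c.value_pct for c in self.components],
            "cumulative_1sd_pct": cum,
        })

    def render(self, k: float | None = None) -> str:
        """Plain-text budget table with the expanded-uncertainty footer."""
        k = self.coverage_factor if k is None else k
        df = self.as_dataframe()
        lines = [f"{'Source of uncertainty':<60}{'Step (1 SD) %':>14}"
                 f"{'Cumulative %':>14}"]
        for _, row in df.iterrows():
            cum = f"{row.cumulative_1sd_pct:.2f}"
            lines.append(f"{row.source:<60}{row.for_step_1sd_pct:>14.2f}"
                         f"{cum:>14}")
        lines.append(f"{f'Combined expanded uncertainty (k={k:g})':<60}"
                     f"{'':>14}{self.expanded(k):>14.2f}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.as_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path | io.StringIO,
                 coverage_factor: float = 2.0) -> "UncertaintyBudget":
        df = pd.read_csv(path)
        budget = cls(coverage_factor=coverage_factor)
        for _, row in df.iterrows():
            budget.add(str(row["source"]), float(row["for_step_1sd_pct"]))
        return budget

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "coverage_factor": self.coverage_factor,
            "components": [{"label": c.label, "value_pct": c.value_pct}
                           for c in self.components]}, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "UncertaintyBudget":
        payload = json.loads(Path(path).read_text())
        budget = cls(coverage_factor=payload.get("coverage_factor", 2.0))
        for c in payload["components"]:
            budget.add(c["label"], c["value_pct"])
        return budget


def absolute_dose_budget() -> UncertaintyBudget:
    """The shipped three-step budget for absolute film dosimetry.

    Step 1: reference absorbed dose to water measured with an ionization
    chamber in the calibration beam; Step 2: film calibration (central
    scoring area); Step 3: dose measurement with film on the full scanning
    area. Values are relative standard uncertainties at ~2 Gy.
    """
    return (UncertaintyBudget(coverage_factor=2.0)
            .add("Step 1: IC reference dose in calibration beam", 1.40)
            .add("Step 2: film calibration (35 mm x 40 mm scoring area)", 0.71)
            .add("Step 3: film dose measurement, full scanning area", 1.00))
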