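"""Agreement statistics between expert and automated differential counts.

A method-comparison study pairs, per individual, the expert's per-class
leukocyte counts with the tool's.  Agreement is summarized per class by
the coefficient of determination R^2 (squared Pearson correlation of the
13 expert/tool count pairs) and overall by a Bland-Altman analysis of
per-individual total counts (mean difference and 95% limits of agreement
mean +/- 1.96 sd).

A packaged fixture ships the published 13-individual, five-class
expert-vs-tool count table this package's validation reproduces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .classification import WBCClass
from .errors import InsufficientDataError, UndefinedCorrelationError

CLASS_ORDER = [
    WBCClass.LYMPHOCYTE,
    WBCClass.NEUTROPHIL,
    WBCClass.BASOPHIL,
    WBCClass.MONOCYTE,
    WBCClass.EOSINOPHIL,
]


@dataclass(frozen=True)
class PairedCounts:
    """Per-individual, per-class counts from two raters over one cohort.

    ``expert`` and ``tool`` are DataFrames indexed by individual with one
    column per leukocyte class (class names).
    """

    expert: pd.DataFrame
    tool: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expert.index) != list(self.tool.index):
            raise ValueError("expert and tool cover different individuals")
        if list(self.expert.columns) != list(self.tool.columns):
            raise ValueError("expert and tool cover different classes")
        for df in (self.expert, self.tool):
            if (df.to_numpy() < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def individuals(self) -> list:
        return list(self.expert.index)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedCounts":
        """Build from long format: columns individual, wbc_class, expert, tool."""
        required = {"individual", "wbc_class", "expert", "tool"}
        if not required.issubset(df.columns):
            raise ValueError(f"need columns {sorted(required)}")
        expert = df.pivot(index="individual", columns="wbc_class", values="expert")
        tool = df.pivot(index="individual", columns="wbc_class", values="tool")
        cols = [c.name for c in CLASS_ORDER if c.name in expert.columns]
        return cls(expert=expert[cols].astype(int), tool=tool[cols].astype(int))

    @classmethod
    def from_csv(cls, path) -> "PairedCounts":
        return cls.from_frame(pd.read_csv(path))


def published_fixture() -> PairedCounts:
    """The packaged 13-individual expert-vs-tool count table."""
    ref = resources.files("leukocount.data").joinpath("expert_tool_counts.csv")
    with ref.open("r") as fh:
        return PairedCounts.from_frame(pd.read_csv(fh))


def r_squared(x, y) -> float:
    """Coefficient of determination: squared Pearson correlation.

    Identical vectors score 1.0 by the perfect-agreement convention even
    when constant (a rater pair that always agrees has nothing left to
    explain); a constant vector paired with a non-identical one has no
    defined correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length vectors")
    if np.array_equal(x, y):
        return 1.0
    if x.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    sx = x - x.mean()
    sy = y - y.mean()
    sxx = float(sx @ sx)
    syy = float(sy @ sy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    sxy = float(sx @ sy)
    return sxy * sxy / (sxx * syy)


def bland_altman(x, y) -> dict[str, float]:
    """Bland-Altman summary of paired differences d = x - y.

    Returns mean difference, sample sd (n-1 denominator), and the 95%
    limits of agreement mean +/- 1.96 sd.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InsufficientDataError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_difference": mean,
        "sd_difference": sd,
        "loa_low": mean - 1.96 * sd,
        "loa_high": mean + 1.96 * sd,
    }


@dataclass(frozen=True)
class ValidationReport:
    """Per-class and overall agreement of tool vs expert counts."""

    per_class_r2_pct: dict[str, float | None]
    per_individual_totals_r2: float
    bland_altman_totals: dict[str, float]
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_class_r2_pct": self.per_class_r2_pct,
                "per_individual_totals_r2": self.per_individual_totals_r2,
                "bland_altman_totals": self.bland_altman_totals,
                "warnings": list(self.warnings),
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = ["Per-class agreement (R^2, %):"]
        for cls, val in self.per_class_r2_pct.items():
            lines.append(
                f"  {cls:<12} {'undefined' if val is None else f'{val:6.2f}'}"
            )
        lines.append(
            f"Per-individual totals R^2: {self.per_individual_totals_r2:.4f}"
        )
        ba = self.bland_altman_totals
        lines.append(
            "Bland-Altman (expert - tool totals): "
            f"mean {ba['mean_difference']:+.3f}, sd {ba['sd_difference']:.3f}, "
            f"95% limits [{ba['loa_low']:+.3f}, {ba['loa_high']:+.3f}]"
        )
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def per_class_agreement(pc: PairedCounts) -> ValidationReport:
    """Per-class R^2 (as percentages) plus totals R^2 and Bland-Altman.

    A class whose correlation is undefined (constant, non-identical
    columns) is reported as missing with a warning rather than failing
    the whole report.
    """
    per_class: dict[str, float | None] = {}
    warnings: list[str] = []
    for col in pc.expert.columns:
        try:
            per_class[col] = 100.0 * r_squared(pc.expert[col], pc.tool[col])
        except UndefinedCorrelationError:
            per_class[col] = None
            warnings.append(f"{col}: correlation undefined (constant counts)")
    expert_totals = pc.expert.sum(axis=1).to_numpy()
    tool_totals = pc.tool.sum(axis=1).to_numpy()
    totals_r2 = r_squared(expert_totals, tool_totals)
    ba = bland_altman(expert_totals, tool_totals)
    return ValidationReport(
        per_class_r2_pct=per_class,
        per_individual_totals_r2=totals_r2,
        bland_altman_totals=ba,
        warnings=tuple(warnings),
    )
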