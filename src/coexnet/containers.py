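"""Shared in-memory containers used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ExpressionMatrix:
    """A gene-by-sample matrix of log-scale expression with a two-group label.

    ``values`` has genes as rows and samples as columns. ``condition`` maps
    every sample id to ``"A"`` (reference / stable) or ``"B"`` (case /
    unstable). Values are assumed already normalized and on a log scale, so
    group mean differences are log fold changes.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        self.condition = pd.Series(self.condition)
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing[:5]}")
        self.condition = self.condition.loc[list(self.values.columns)]
        bad = set(self.condition.unique()) - {"A", "B"}
        if bad:
            raise ValueError(f"condition labels must be 'A' or 'B', got {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list:
        return list(self.condition.index[self.condition == condition])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.condition.copy())


@dataclass
class ModulePartition:
    """Gene-to-module assignment with optional module eigengenes.

    ``assignment`` maps every gene to an integer module label; label 0 means
    unassigned (grey). ``eigengenes`` is a module-by-sample matrix of first
    principal components, sign-aligned so each eigengene correlates
    positively with its module's mean expression profile.
    """

    assignment: pd.Series
    eigengenes: pd.DataFrame | None = None
    variance_explained: pd.Series | None = None

    @property
    def module_labels(self) -> list[int]:
        labels = sorted(set(self.assignment) - {0})
        return [int(m) for m in labels]

    def module_genes(self, label: int) -> list:
        return list(self.assignment.index[self.assignment == label])

    def sizes(self) -> pd.Series:
        counts = self.assignment[self.assignment != 0].value_counts()
        return counts.sort_index()


@dataclass
class EdgeTable:
    """Weighted, optionally directed edges with provenance columns."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["source", "target", "weight"])
    )
    directed: bool = True

    def __len__(self) -> int:
        return len(self.edges)
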