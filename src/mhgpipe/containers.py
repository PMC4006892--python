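"""In-memory containers shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, InputError


@dataclass
class ExpressionMatrix:
    """A probes x samples matrix of log2-scale intensities.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id.
    genes
        Series mapping probe id -> gene symbol, aligned to ``values.index``.
        Probes with no annotation carry NaN/empty; they are dropped (with a
        logged count) at the probe-collapsing step, not here.
    groups
        Series mapping sample id -> group label. Differential analysis
        requires exactly two distinct labels.
    """

    values: pd.DataFrame
    genes: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise InputError(f"duplicate probe ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:3].tolist()
            raise InputError(f"duplicate sample ids: {dup}")
        if self.values.isna().any().any():
            n = int(self.values.isna().sum().sum())
            raise InputError(f"expression matrix contains {n} missing values")
        self.genes = self.genes.reindex(self.values.index)
        missing = self.groups.index.symmetric_difference(self.values.columns)
        if len(missing):
            raise InputError(f"group labels do not match sample ids: {list(missing)[:5]}")
        # keep group labels in sample-column order
        self.groups = self.groups.reindex(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_names(self) -> list[str]:
        """Distinct group labels in order of first appearance among samples."""
        return list(dict.fromkeys(self.groups))

    def two_groups(self, control: str | None = None, treated: str | None = None) -> tuple[str, str]:
        """Resolve (control, treated) labels; defaults to appearance order."""
        names = self.group_names()
        if control is None and treated is None:
            if len(names) != 2:
                raise DesignError(f"expected exactly two groups, found {names}")
            return names[0], names[1]
        if control is None or treated is None:
            other = [g for g in names if g != (control or treated)]
            if len(other) != 1:
                raise DesignError(f"cannot infer second group from labels {names}")
            return (other[0], treated) if control is None else (control, other[0])
        for g in (control, treated):
            if g not in names:
                raise DesignError(f"group {g!r} not present among labels {names}")
        return control, treated

    def group_values(self, group: str) -> np.ndarray:
        cols = self.groups.index[self.groups == group]
        return self.values[cols].to_numpy(dtype=float)

    def subset_probes(self, mask) -> "ExpressionMatrix":
        """Row-subset preserving order; mask is boolean per probe."""
        return ExpressionMatrix(
            values=self.values.loc[mask],
            genes=self.genes.loc[mask],
            groups=self.groups.copy(),
        )


@dataclass
class GroundTruth:
    """Simulation ground truth: one record per simulated entity."""

    probe_fold: pd.Series  # realized treated/control ratio per probe (1.0 = null)
    probe_de: pd.Series  # bool per probe
    gene_fold: pd.Series  # realized ratio per gene
    gene_de: pd.Series  # bool per gene
    set_enriched: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    target_rq: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """Flat per-entity table (entity_type, entity_id, fold/rq, de_flag)."""
        parts = [
            pd.DataFrame(
                {
                    "entity_type": "probe",
                    "entity_id": self.probe_fold.index,
                    "true_fold": self.probe_fold.to_numpy(),
                    "true_flag": self.probe_de.to_numpy(),
                }
            ),
            pd.DataFrame(
                {
                    "entity_type": "gene",
                    "entity_id": self.gene_fold.index,
                    "true_fold": self.gene_fold.to_numpy(),
                    "true_flag": self.gene_de.to_numpy(),
                }
            ),
        ]
        if len(self.set_enriched):
            parts.append(
                pd.DataFrame(
                    {
                        "entity_type": "gene_set",
                        "entity_id": self.set_enriched.index,
                        "true_fold": np.nan,
                        "true_flag": self.set_enriched.to_numpy(),
                    }
                )
            )
        if len(self.target_rq):
            parts.append(
                pd.DataFrame(
                    {
                        "entity_type": "qpcr_target",
                        "entity_id": self.target_rq.index,
                        "true_fold": self.target_rq.to_numpy(),
                        "true_flag": self.target_rq.to_numpy() != 1.0,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


@dataclass
class GeneSet:
    """A named set of gene identifiers (one GMT line)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        # preserve order but drop duplicate members
        self.members = tuple(dict.fromkeys(self.members))
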