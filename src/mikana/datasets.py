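"""Expression-data container shared by the simulator, the regressions and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "STEADY_STATE", "TIME_SERIES", "META_COLUMNS"]

STEADY_STATE = "steady_state"
TIME_SERIES = "time_series"

#: canonical sample-metadata columns (sidecar TSV order)
META_COLUMNS = [
    "sample_id", "kind", "replicate", "time_h",
    "perturbed_gene", "knockdown_fraction", "noise_level",
]


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with per-sample metadata.

    ``values`` has one row per gene (order given by ``genes``) and one column
    per sample.  ``meta`` is a DataFrame with one row per sample column, in
    column order, carrying the :data:`META_COLUMNS` fields:

    - ``kind``: ``"steady_state"`` (post-knockdown equilibrium) or
      ``"time_series"`` (trajectory sample);
    - ``perturbed_gene`` / ``knockdown_fraction``: which gene the siRNA-style
      clamp targeted and the knockdown fraction δ ∈ [0, 1] (steady state only);
    - ``replicate`` / ``time_h``: replicate id and sampling time in hours
      (time series only);
    - ``noise_level``: fractional measurement-noise level applied.
    """

    values: np.ndarray
    genes: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = list(self.genes)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if self.values.shape[0] != len(self.genes):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.genes)} gene names"
            )
        self.meta = self.meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(self.meta) != self.values.shape[1]:
            raise ValueError(
                f"{self.values.shape[1]} sample columns but "
                f"{len(self.meta)} metadata rows"
            )
        if self.meta["sample_id"].duplicated().any():
            dupes = self.meta.loc[self.meta["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicated sample ids: {sorted(set(dupes))[:5]}")
        bad_kind = set(self.meta["kind"]) - {STEADY_STATE, TIME_SERIES}
        if bad_kind:
            raise ValueError(f"unknown sample kinds: {sorted(bad_kind)}")
        self._check_steady_state()
        self._check_time_series()

    def _check_steady_state(self) -> None:
        ss = self.meta[self.meta["kind"] == STEADY_STATE]
        if ss["perturbed_gene"].isna().any():
            raise ValueError("steady-state samples must name a perturbed gene")
        frac = ss["knockdown_fraction"].astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("knockdown_fraction must lie in [0, 1]")

    def _check_time_series(self) -> None:
        ts = self.meta[self.meta["kind"] == TIME_SERIES]
        for rep, grp in ts.groupby("replicate"):
            t = grp["time_h"].astype(float).to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"time points not strictly increasing in replicate {rep!r}"
                )

    # -- queries ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def kinds(self) -> pd.Series:
        return self.meta["kind"]

    def is_empty(self) -> bool:
        return self.n_samples == 0

    def gene_index(self, gene: int | str) -> int:
        if isinstance(gene, str):
            try:
                return self.genes.index(gene)
            except ValueError:
                raise KeyError(f"unknown gene {gene!r}") from None
        return int(gene)

    def subset(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        return ExpressionDataset(
            values=self.values[:, mask],
            genes=self.genes,
            meta=self.meta.loc[np.asarray(mask)].reset_index(drop=True),
        )

    def steady_state(self) -> "ExpressionDataset":
        return self.subset((self.meta["kind"] == STEADY_STATE).to_numpy())

    def time_series(self) -> "ExpressionDataset":
        return self.subset((self.meta["kind"] == TIME_SERIES).to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genes, columns=self.meta["sample_id"]
        )

    # -- construction helpers --------------------------------------------
    @classmethod
    def empty(cls, genes: list[str]) -> "ExpressionDataset":
        return cls(
            values=np.zeros((len(genes), 0)),
            genes=genes,
            meta=pd.DataFrame(columns=META_COLUMNS),
        )

    @classmethod
    def concat(cls, parts: list["ExpressionDataset"]) -> "ExpressionDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        genes = parts[0].genes
        for p in parts[1:]:
            if p.genes != genes:
                raise ValueError("gene lists differ between datasets")
        nonempty = [p for p in parts if not p.is_empty()]
        if not nonempty:
            return cls.empty(genes)
        return cls(
            values=np.concatenate([p.values for p in nonempty], axis=1),
            genes=genes,
            meta=pd.concat([p.meta for p in nonempty], ignore_index=True),
        )
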