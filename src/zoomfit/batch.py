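"""Container pairing a design matrix with per-row output metric vectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class SimulationBatch:
    """The X/Y of every metamodel: parameters per row, metrics per row.

    ``params`` and ``metrics`` share an index (one row per simulation);
    metric entries may be NaN when a descriptor was undefined for that run
    (e.g. relaxation never reached within the record).  ``errors`` records
    rows whose simulation failed outright and therefore have no metrics.
    """

    params: pd.DataFrame
    metrics: pd.DataFrame
    errors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.params.index.equals(self.metrics.index):
            raise ValueError("params and metrics must share an index")

    @property
    def n(self) -> int:
        return len(self.params)

    @property
    def complete_mask(self) -> pd.Series:
        """Rows whose metric vector has no missing entries."""
        return self.metrics.notna().all(axis=1)

    def complete(self) -> "SimulationBatch":
        m = self.complete_mask
        return SimulationBatch(self.params.loc[m], self.metrics.loc[m], dict(self.errors))
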