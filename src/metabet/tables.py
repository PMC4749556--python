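"""Packaged verbatim transcriptions of the published group-result tables.

Table 1: each subject's interpolated probability of betting on the
target-present interval at 75% correct orientation discrimination (12 rows;
the three subjects who completed both experiments appear once per experiment
and are treated as independent units, as in the original analysis).

Table 2: goodness of fit (R^2) of the ideal observer (sigma_d = 0) and three
decisional-noise variants (sigma_d = 0.1, 0.2, 0.3) for the same 12 units.

The published summary statistics are kept alongside so that recomputation can
be checked against them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

_CHECKSUMS = {
    "table1_bet_at_75.csv": "fc066d3ba0cc1a08731914eb45955ed04aaa27b4747f56154371a74433e56552",
    "table2_r2_by_noise.csv": "ffe70066f5ab9959e7f1a4223f71c11ae6cb868e586505ac7873185d590b8305",
}

SIGMA_GRID = (0.0, 0.1, 0.2, 0.3)

#: published summary rows, for comparison only (never used in recomputation)
PRINTED = {
    "table1_mean": 0.686,
    "table1_sd": 0.033,
    "table1_abs_t": 6.718,
    "table1_df": 11,
    "table1_p": 0.00003,
    "table2_col_means": (0.565, 0.563, 0.555, 0.539),
    "table2_col_sds": (0.126, 0.128, 0.129, 0.131),
    "anova_F": 19.301,
    "anova_df": (3, 33),
}


@dataclass(frozen=True)
class PrintedTables:
    table1: pd.DataFrame  # experiment, subject, bet_tp_at_75
    table2: pd.DataFrame  # experiment, subject, r2 at each sigma_d

    @property
    def table1_values(self) -> np.ndarray:
        return self.table1["bet_tp_at_75"].to_numpy(dtype=float)

    @property
    def table2_matrix(self) -> np.ndarray:
        """12 x 4 R^2 matrix, columns ordered by sigma_d."""
        cols = [f"r2_sigma_{s}" for s in SIGMA_GRID]
        return self.table2[cols].to_numpy(dtype=float)


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("metabet.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} checksum mismatch ({digest}); transcription corrupted"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_printed_tables() -> PrintedTables:
    """Load (and checksum-verify) the packaged table transcriptions."""
    t1 = _read_fixture("table1_bet_at_75.csv")
    t2 = _read_fixture("table2_r2_by_noise.csv")
    if len(t1) != 12 or len(t2) != 12:
        raise RuntimeError("each printed table must have exactly 12 subject rows")
    return PrintedTables(table1=t1, table2=t2)
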