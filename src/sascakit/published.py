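"""Reference fitted-parameter tables for single-cell DNR uptake.

Published single-cell kinetic parameters for CCRF-CEM leukemia cells:
one- and two-exponential fits for five drug-sensitive CEM/WT cells
(``WT_FITS``), two-exponential fits for twenty multidrug-resistant
CEM/VLB cells without inhibitor (``VLB_FITS``) and four with
cyclosporine A (``VLB_CSA_FITS``), and paired same-single-cell
control/inhibitor fits for three CEM/VLB cells (``SASCA_FITS``).

These tables serve as worked examples: their parameter rows define
noiseless synthetic inputs for parameter-recovery checks, and their
columns are the ground truth for cross-cell heterogeneity summaries.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "WT_FITS",
    "VLB_FITS",
    "VLB_CSA_FITS",
    "SASCA_FITS",
    "wt_one_exp_params",
    "vlb_two_exp_params",
    "sasca_two_exp_params",
]

# One- and two-exponential fits for five CEM/WT cells.
# Columns: one-exp (P, Q, R_one) and two-exp (A, B, C, D, R_two).
WT_FITS = pd.DataFrame(
    [
        ("146", "CEM/WT", 2.7140, 0.0007, 0.9812, 2.7000, 0.0007, 0.1000, 0.0002, 0.9778),
        ("147", "CEM/WT", 3.7468, 0.0002, 0.9241, 2.8000, 0.0002, 0.3000, 0.0003, 0.9230),
        ("148", "CEM/WT", 2.8010, 0.0008, 0.9715, 3.0700, 0.0004, 0.5000, 0.0025, 0.9712),
        ("149", "CEM/WT", 2.8184, 0.0004, 0.9685, 3.0376, 0.0003, 0.3150, 0.0006, 0.9665),
        ("154", "CEM/WT", 2.3556, 0.0007, 0.9490, 3.3500, 0.0003, 0.3500, 0.0006, 0.9306),
    ],
    columns=["cell_id", "cell_type", "P", "Q", "R_one", "A", "B", "C", "D", "R_two"],
)

# Two-exponential fits for twenty CEM/VLB cells, no inhibitor.
VLB_FITS = pd.DataFrame(
    [
        ("10", "CEM/VLB", 0.0768, 0.0442, 0.4581, 0.0020, 0.9757),
        ("11", "CEM/VLB", 0.4455, 0.0400, 0.6000, 0.0010, 0.9520),
        ("24", "CEM/VLB", 0.7980, 0.0100, 0.7000, 0.0051, 0.9306),
        ("56", "CEM/VLB", 0.3272, 0.0405, 0.2000, 0.0003, 0.8597),
        ("58", "CEM/VLB", 0.4378, 0.0556, 0.4905, 0.0046, 0.9865),
        ("69", "CEM/VLB", 0.3495, 0.0517, 0.1563, 0.0017, 0.8774),
        ("70-01", "CEM/VLB", 0.1495, 0.0143, 0.1147, 0.0013, 0.7012),
        ("70-03", "CEM/VLB", 0.2011, 0.1483, 0.3897, 0.0032, 0.8513),
        ("70-07", "CEM/VLB", 0.1150, 0.2720, 0.5339, 0.0026, 0.8878),
        ("70-08", "CEM/VLB", 0.3540, 0.0264, 0.4782, 0.0011, 0.8894),
        ("70-11", "CEM/VLB", 0.3000, 0.0864, 0.4000, 0.0014, 0.8551),
        ("70-12", "CEM/VLB", 0.3145, 0.0815, 0.3005, 0.0006, 0.7385),
        ("70-18", "CEM/VLB", 0.4303, 0.0269, 0.3182, 0.0009, 0.8770),
        ("70-19", "CEM/VLB", 0.3191, 0.1375, 0.2646, 0.0022, 0.7717),
        ("70-23", "CEM/VLB", 0.6220, 0.0100, 0.4000, 0.0023, 0.9095),
        ("70-25", "CEM/VLB", 0.6922, 0.1792, 0.8048, 0.0016, 0.8822),
        ("76", "CEM/VLB", 0.1975, 0.0835, 0.2269, 0.0134, 0.7056),
        ("77", "CEM/VLB", 0.3040, 0.0894, 0.3337, 0.0081, 0.7817),
        ("88", "CEM/VLB", 0.4827, 0.2513, 0.4565, 0.0037, 0.8593),
        ("95", "CEM/VLB", 0.2510, 0.0040, 0.1352, 0.0007, 0.9140),
    ],
    columns=["cell_id", "cell_type", "A", "B", "C", "D", "R"],
)
VLB_FITS["A_plus_C"] = VLB_FITS["A"] + VLB_FITS["C"]

# Two-exponential fits for four CEM/VLB cells in the presence of CsA.
# The plateau column A_plus_C is recomputed from A and C.
VLB_CSA_FITS = pd.DataFrame(
    [
        ("150", "CEM/VLB CsA", 0.6109, 0.1526, 0.6066, 0.0014, 0.8682),
        ("151", "CEM/VLB CsA", 0.5281, 0.0150, 0.7463, 0.0070, 0.8911),
        ("152", "CEM/VLB CsA", 0.7277, 0.0293, 0.2146, 0.0015, 0.7740),
        ("153", "CEM/VLB CsA", 0.4251, 0.0446, 0.2692, 0.0014, 0.7730),
    ],
    columns=["cell_id", "cell_type", "A", "B", "C", "D", "R"],
)
VLB_CSA_FITS["A_plus_C"] = VLB_CSA_FITS["A"] + VLB_CSA_FITS["C"]

# Paired same-single-cell (SASCA) fits: control phase, then the
# incremental uptake phase after switching to DNR plus MDR inhibitor.
SASCA_FITS = pd.DataFrame(
    [
        ("58", "control", 0.4378, 0.0556, 0.4905, 0.0046),
        ("58", "inhibitor", 0.1614, 0.0973, 0.3972, 0.0053),
        ("70-08", "control", 0.3540, 0.0264, 0.4782, 0.0011),
        ("70-08", "inhibitor", 0.2055, 0.0371, 0.2454, 0.0060),
        ("95", "control", 0.2510, 0.0040, 0.1352, 0.0007),
        ("95", "inhibitor", 0.2681, 0.0050, 0.1000, 0.0080),
    ],
    columns=["cell_id", "phase", "A", "B", "C", "D"],
)


def wt_one_exp_params(cell_id: str) -> tuple[float, float]:
    """(P, Q) for one CEM/WT cell from the one-exponential fit table."""
    row = WT_FITS.loc[WT_FITS["cell_id"] == cell_id]
    if row.empty:
        raise KeyError(f"no CEM/WT cell {cell_id!r}")
    return float(row["P"].iloc[0]), float(row["Q"].iloc[0])


def vlb_two_exp_params(cell_id: str) -> tuple[float, float, float, float]:
    """(A, B, C, D) for one CEM/VLB cell (no inhibitor)."""
    row = VLB_FITS.loc[VLB_FITS["cell_id"] == cell_id]
    if row.empty:
        raise KeyError(f"no CEM/VLB cell {cell_id!r}")
    return tuple(float(row[c].iloc[0]) for c in "ABCD")  # type: ignore[return-value]


def sasca_two_exp_params(cell_id: str, phase: str) -> tuple[float, float, float, float]:
    """(A, B, C, D) for one SASCA phase ('control' or 'inhibitor')."""
    row = SASCA_FITS.loc[(SASCA_FITS["cell_id"] == cell_id) & (SASCA_FITS["phase"] == phase)]
    if row.empty:
        raise KeyError(f"no SASCA record for cell {cell_id!r}, phase {phase!r}")
    return tuple(float(row[c].iloc[0]) for c in "ABCD")  # type: ignore[return-value]
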