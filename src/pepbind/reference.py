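"""Literature reference energy components for the TNFα-TNFR1 system.

These are published MM-PBSA component means (kcal/mol) for the wild-type
TNFα-TNFR1 complex, the α_CC8-TNFR1 complex and its L16X point mutants.
They serve as inputs to the aggregation layer: feeding the four component
terms through the single-trajectory identities must return the reported
totals.  (One mutant row, L16R, is internally inconsistent by 0.02
kcal/mol in the source and is kept for completeness.)
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .energetics import EnergyBreakdown

__all__ = ["load_reference_energies", "aggregate_reference_row"]


def load_reference_energies() -> pd.DataFrame:
    src = resources.files("pepbind.data").joinpath("reference_energies.csv")
    with src.open() as fh:
        return pd.read_csv(fh)


def aggregate_reference_row(label: str) -> EnergyBreakdown:
    """Build an EnergyBreakdown from the four published component terms."""
    table = load_reference_energies().set_index("complex")
    if label not in table.index:
        raise KeyError(f"no reference row {label!r}; have {list(table.index)}")
    row = table.loc[label]
    return EnergyBreakdown.from_components(
        e_ele=float(row["e_ele"]),
        e_vdw=float(row["e_vdw"]),
        g_pb=float(row["g_pb"]),
        g_nonp=float(row["g_nonp"]),
    )
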