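"""Bundled reference data.

``load_reference_correlations`` returns the regional twin-correlation and
variance-component table from a published two-site twin cohort
(33 MZ and 48 DZ adolescent/young-adult pairs; 42 JHU ICBM-DTI-81 regions
x 4 DTI metrics).  It is shipped as a worked-example input — the
correlation columns can be fed straight into the biometric fitting stage —
and as a validation surface for the summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_correlations", "REFERENCE_N_MZ", "REFERENCE_N_DZ"]

#: Pair counts of the reference cohort.
REFERENCE_N_MZ = 33
REFERENCE_N_DZ = 48


def load_reference_correlations() -> pd.DataFrame:
    """Long table: metric, region, r_mz, r_dz, p, model, A, C, D, A_plus_D, G, E, total."""
    with resources.files("twindti.data").joinpath(
        "reference_twin_correlations.csv"
    ).open() as fh:
        return pd.read_csv(fh)
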