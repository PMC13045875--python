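"""JHU ICBM-DTI-81 white-matter atlas bookkeeping.

The ICBM-DTI-81 atlas labels 48 white-matter tract regions on the 1 mm
MNI/FMRIB58 grid (label 0 = background).  Region abbreviations follow the
conventional short codes used in TBSS studies, with ``_R``/``_L`` hemisphere
suffixes for bilaterally defined tracts.

Six regions in the posterior fossa — the middle cerebellar peduncle, the
pontine crossing tract, and the bilateral medial lemniscus and inferior
cerebellar peduncle — are commonly dropped from skeleton-based analyses
because of poor skeleton coverage and susceptibility artefacts; the module
exposes that set as :data:`DEFAULT_EXCLUSIONS`, leaving 42 analysable
regions.
"""

from __future__ import annotations

import json
from pathlib import Path

# label index -> short region code, FSL JHU-labels ordering
JHU_LABELS: dict[int, str] = {
    1: "MCP",
    2: "PCT",
    3: "gCC",
    4: "bCC",
    5: "sCC",
    6: "FX",
    7: "CST_R",
    8: "CST_L",
    9: "ML_R",
    10: "ML_L",
    11: "ICP_R",
    12: "ICP_L",
    13: "SCP_R",
    14: "SCP_L",
    15: "CP_R",
    16: "CP_L",
    17: "ALIC_R",
    18: "ALIC_L",
    19: "PLIC_R",
    20: "PLIC_L",
    21: "RIC_R",
    22: "RIC_L",
    23: "ACR_R",
    24: "ACR_L",
    25: "SCR_R",
    26: "SCR_L",
    27: "PCR_R",
    28: "PCR_L",
    29: "PTR_R",
    30: "PTR_L",
    31: "SS_R",
    32: "SS_L",
    33: "EC_R",
    34: "EC_L",
    35: "CgC_R",
    36: "CgC_L",
    37: "CgH_R",
    38: "CgH_L",
    39: "FX/ST_R",
    40: "FX/ST_L",
    41: "SLF_R",
    42: "SLF_L",
    43: "SFOF_R",
    44: "SFOF_L",
    45: "UF_R",
    46: "UF_L",
    47: "TAP_R",
    48: "TAP_L",
}

#: Posterior-fossa regions with poor TBSS skeleton representation.
DEFAULT_EXCLUSIONS: frozenset[str] = frozenset(
    {"MCP", "PCT", "ML_R", "ML_L", "ICP_R", "ICP_L"}
)

#: The 42 regions retained for twin analysis, in atlas label order.
ANALYSIS_REGIONS: tuple[str, ...] = tuple(
    name for _, name in sorted(JHU_LABELS.items()) if name not in DEFAULT_EXCLUSIONS
)

METRICS: tuple[str, ...] = ("FA", "MD", "AD", "RD")


def load_label_names(path: str | Path) -> dict[int, str]:
    """Read a label → region-name map from JSON or an FSL-style XML label list.

    JSON files map label indices (as strings or ints) to names.  XML files
    follow the FSL atlas convention: ``<label index="3" ...>name</label>``,
    where the stored index is the label value minus one.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {int(k): str(v) for k, v in raw.items()}
    if path.suffix.lower() == ".xml":
        import xml.etree.ElementTree as ET

        root = ET.parse(path).getroot()
        out: dict[int, str] = {}
        for el in root.iter("label"):
            out[int(el.get("index")) + 1] = (el.text or "").strip()
        if not out:
            raise ValueError(f"no <label> entries found in {path}")
        return out
    raise ValueError(f"unsupported label-name format: {path.suffix!r}")
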