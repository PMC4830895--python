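"""Published per-drug summary of hepatotoxicant modulation of Nrf2 and
NF-κB signalling in the HepG2 reporter panel.

Columns: Srxn1-GFP fold induction at 24 h, delay (minutes) of the second
NF-κB nuclear translocation upon TNFα, percent apoptotic cells at 24 h for
drug alone and with TNFα added for the final 16 h, and the resulting TNFα
enhancement in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

__all__ = ["DrugSummary", "DRUG_PANEL"]


@dataclass(frozen=True)
class DrugSummary:
    name: str
    fold_induction: float
    delay_min: float
    pct_dead: float
    pct_dead_tnf: float
    synergy: float


DRUG_PANEL: Dict[str, DrugSummary] = {
    "TGZ": DrugSummary("Troglitazone", 1.3, 2, 1.1, 2.6, 1.5),
    "INH": DrugSummary("Isoniazid", 1.0, 2, 2.8, 3.3, 0.5),
    "OFX": DrugSummary("Ofloxacin", 1.1, 8, 2.3, 3.2, 0.9),
    "SN": DrugSummary("Simvastatin", 1.1, 2, 2.5, 3.6, 1.1),
    "NPX": DrugSummary("Naproxen", 1.8, 4, 2.1, 2.3, 0.2),
    "MTX": DrugSummary("Methotrexate", 3.3, 9, 1.9, 1.9, 0.0),
    "AMI": DrugSummary("Amiodarone", 1.9, 22, 5.8, 9.0, 3.2),
    "APAP": DrugSummary("Acetaminophen", 4.0, 4, 2.5, 2.5, 0.0),
    "AMAP": DrugSummary("3'-Hydroxyacetanilide", 4.0, 4, 3.1, 3.4, 0.3),
    "NTF": DrugSummary("Nitrofurantoin", 4.6, 29, 2.9, 3.6, 0.7),
    "NFZ": DrugSummary("Nefazodone", 4.8, 22, 3.5, 6.8, 3.3),
    "CLZ": DrugSummary("Clozapine", 4.6, 12, 4.0, 7.7, 3.7),
    "CBZ": DrugSummary("Carbamazepine", 4.1, 20, 3.9, 22.5, 18.6),
    "DCF": DrugSummary("Diclofenac", 6.7, 26, 4.5, 14.2, 9.7),
    "KTZ": DrugSummary("Ketoconazole", 8.3, 26, 5.0, 8.1, 3.1),
}
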