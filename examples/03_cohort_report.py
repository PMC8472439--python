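"""Render the diagnostic-yield report for the bundled cohort.

Shows the overall and per-category yield, the share of diagnoses that
required the CNV pipeline, the size-class partition of the diagnostic
CNVs, and the microarray-VUS concordance breakdown.
"""

import pandas as pd

from exocnv import size_class
from exocnv.cohort_report import acgh_concordance, render_report, size_class_summary
from exocnv.fixtures import acgh_vus_frame, cohort_records, table1_calls

sizes = size_class_summary(pd.DataFrame({
    "patient_id": [f"case{c}" for c, _ in table1_calls()],
    "size_class": [size_class(call) for _, call in table1_calls()],
}))
print(render_report(cohort_records(), size_classes=sizes))

conc = acgh_concordance(acgh_vus_frame())
print(f"\nMicroarray VUS re-examined in sequencing data: {conc['n']}")
print(f"  detected:               {conc['detected']}")
print(f"  no capture targets:     {conc['undetected']['no_ngs_targets']}")
print(f"  polymorphic (filtered): {conc['undetected']['polymorphic']}")
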