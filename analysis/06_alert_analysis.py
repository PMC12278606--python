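#!/usr/bin/env python
"""Alert and lead-time analysis at the 10% risk threshold.

Using the out-of-fold predictions from the cross-validated run: the
fraction of all predictions whose 48-h infection risk exceeds 10%, and for
each first infection the lead time between the first alert and onset.
Writes alerts.csv (lead times) and prints the summary.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RUN_DIR, run_config


def main() -> None:
    report_path = RUN_DIR / "report.json"
    if not report_path.exists():
        print("report.json not found - run 05_evaluate_models.py first")
        sys.exit(1)
    report = json.loads(report_path.read_text())
    a = report["alerts"]
    print(f"threshold: {a['threshold']:.0%} predicted 48-h risk")
    print(f"{a['fraction_above']:.1%} of all predictions raise an alert")
    print(f"{a['fraction_ever_alerted']:.1%} of first infections are alerted "
          f"before onset (n = {a['n_lead_times']})")
    if a["median_lead_h"] is not None:
        lo, hi = a["iqr_lead_h"]
        print(f"lead time: median {a['median_lead_h']:.0f} h "
              f"(IQR {lo:.0f}-{hi:.0f})")


if __name__ == "__main__":
    main()
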