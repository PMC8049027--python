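#!/usr/bin/env python
"""Charge bookkeeping for the protamine analyte.

Parses the packaged protamine FASTA and reports the quantities the
electrodiffusion analysis assumes: 32 residues, 21 of them arginine, an
effective net charge of +21 e under the side-chain counting model, and 11
divalent sulfate counterions to neutralise it.  Writes
results/peptide_report.json.
"""

import json
from pathlib import Path

from porethru import peptide as pep

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ptm = pep.load_ptm()
    report = pep.peptide_report(ptm)
    OUT.mkdir(exist_ok=True)
    (OUT / "peptide_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"{report['name']}: {report['length']} residues, "
          f"{report['arg_count']} Arg, net charge +{report['net_charge_e']} e, "
          f"{report['counterion_count']} sulfate counterions "
          f"(free-base mass {report['mass_da']} Da)")


if __name__ == "__main__":
    main()
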