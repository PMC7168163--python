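"""Characterize the bundled reference set of 30 mytilin mature peptides.

Prints each peptide's net charge, isoelectric point and cysteine-array class,
then the family-level summaries: how many Perna peptides carry the CCC
triplet, the charge extremes, and the rows whose reported lengths disagree
with their sequences.
"""

from mytikit.cysarray import count_ccc, detect_array
from mytikit.datasets import load_reference_peptides, perna_peptides, validate_reference_table
from mytikit.physchem import isoelectric_point, net_charge

peptides = load_reference_peptides()
print(f"{'peptide':22s} {'len':>3s} {'charge':>6s} {'pI':>6s}  array")
for pep in peptides:
    report = detect_array(pep)
    klass = report.array_class + ("+CCC" if report.has_ccc else "")
    print(f"{pep.id:22s} {len(pep):3d} {net_charge(pep):+6d} {isoelectric_point(pep):6.2f}  {klass}")

perna = perna_peptides()
print(f"\nPerna peptides with a CCC triplet: {count_ccc(perna)} / {len(perna)}")
print(f"Perna net-charge range: {min(net_charge(p) for p in perna):+d} "
      f"to {max(net_charge(p) for p in perna):+d}")
print("Rows with inconsistent reported lengths:")
for flag in validate_reference_table():
    print(f"  {flag.name}: sequence {flag.sequence_length} aa, reported "
          f"{flag.reported_length}{f' / {flag.reported_length_alt}' if flag.reported_length_alt else ''}"
          f" ({flag.reason})")
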