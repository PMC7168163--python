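"""Reduce a family to unique sequences, build a profile HMM, screen with it.

Mirrors the model-building stage of a discovery study: Hobohm-2 removes
near-duplicates (BLOSUM62 distance < 0.1), the survivors are aligned and
turned into a calibrated profile HMM, and candidate peptides are scored
against a mytilin and a myticin model in parallel so each hit is claimed by
the better-fitting family.
"""

from mytikit.align import progressive_msa
from mytikit.io_formats import Peptide
from mytikit.profile_hmm import build_hmm, calibrate, dual_screen
from mytikit.redundancy import reduce_peptides
from mytikit.synthetic_data import make_mature_family

family = make_mature_family(seed=8, kind="canonical", n=40, prefix="myt")
retained, removals = reduce_peptides(family, threshold=0.1)
print(f"Hobohm-2: {len(family)} -> {len(retained)} sequences "
      f"({len(removals)} near-duplicates removed)")

mytilin_hmm = calibrate(build_hmm(progressive_msa(retained)), n_null=300, seed=8)
myticin_family = make_mature_family(seed=9, kind="myticin_like", n=20, prefix="mtc")
myticin_hmm = calibrate(build_hmm(progressive_msa(myticin_family)), n_null=300, seed=9)
print(f"mytilin model: {mytilin_hmm.length} match states, "
      f"Gumbel mu={mytilin_hmm.calibration[0]:.1f}, lambda={mytilin_hmm.calibration[1]:.3f}")

queries = (
    make_mature_family(seed=8, kind="canonical", n=45, prefix="myt")[40:]  # same family, unseen
    + myticin_family[:3]
    + [Peptide("random_1", "MSTNQGGAPLVKEDDSTNQGAPLVKEDDSTNQG")]
)
print(f"{'query':12s} {'bits':>7s} {'E-value':>9s}  label")
for hit in dual_screen(queries, mytilin_hmm, myticin_hmm, e_threshold=0.05):
    print(f"{hit.peptide_id:12s} {hit.bit_score:7.1f} {hit.e_value:9.2g}  {hit.best_model}")
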