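"""Compute the 1,103-feature descriptor vector for a handful of sequences.

Builds three short protein sequences, featurizes them, and prints the
per-family blocks for the first one.  The amino-acid composition block shows
why ``aac_5`` reads as "fraction of cysteine": feature names index the fixed
ARNDCQEGHILKMFPSTWYV residue order.
"""

import bacpred as bp

seqs = [
    bp.ProteinSequence("nisin_like", "ITSISLCTPGCKTGALMGCNMKTATCHCSIHVSK"),
    bp.ProteinSequence("helical", "MKKLLLLLAAAAEEEEKKKKLLLLAAAAEEEEKK"),
    bp.ProteinSequence("mixed", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQ"),
]

fm = bp.featurize(seqs)
print(f"feature matrix: {fm.n_samples} sequences x {fm.n_features} features")

row = fm.values[0]
names = fm.schema.names
print(f"\n{seqs[0].id}:")
print(f"  aac_5 (cysteine fraction)        = {row[names.index('aac_5')]:.4f}")
print(f"  dist_93 (solvent-acc. buried 50%) = {row[names.index('dist_93')]:.2f}")
print(f"  AAC block sums to                 {row[:20].sum():.6f} (a composition)")
print(f"  QSO block sums to                 {row[names.index('qso_1'):names.index('qso_1')+40].sum():.6f}")

sizes = {}
for n in names:
    sizes[bp.family_of(n)] = sizes.get(bp.family_of(n), 0) + 1
print("\nfamily dimensionalities:", sizes, "| total:", sum(sizes.values()))
# The nine families partition the 1,103-dimensional vector; every
# composition-style family is normalized to sum to 1 per sequence.
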