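"""Generate a complete synthetic bead-array screen with a ground-truth ledger.

The generator plants each antibody as on-target, co-target, off-target or
no-binder, simulates construct expression (with subfamily-dependent failure
rates) and the saturating fluorescence signal, and records every latent
variable so downstream analyses can be benchmarked by parameter recovery.
"""

from collections import Counter

import sbaval as sv

config = sv.SimulationConfig(seed=1)
dataset = sv.generate_dataset(config, outdir="scratch/example_dataset")

classes = Counter(t.planted_class for t in dataset.truth.antibodies.values())
print(f"library: {len(dataset.library)} constructs in "
      f"{len({g.subfamily for g in dataset.library})} subfamily panels")
print(f"samples: {len(dataset.samples)} wells "
      f"({sum(s.is_mock for s in dataset.samples)} mock)")
print(f"antibodies: {config.n_abs} planted as {dict(classes)}")
print(f"failed constructs: {sorted(dataset.truth.failed_constructs)}")
print("files written to scratch/example_dataset/ (TSV matrices, FASTA library,"
      " JSON truth ledger)")
# The planted class mix mirrors the outcome distribution typical of large
# polyclonal antibody screens: ~61% selective, ~12% cross-reactive, ~27% silent.
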