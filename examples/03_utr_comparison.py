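"""Effect of untranslated regions in the index on estimated allele TPM.

Reads are simulated from full transcripts (CDS plus UTRs) and quantified
twice: against an index whose allele entries are bare coding sequences,
and against one carrying the UTRs as well.  When only the CDS is
indexed, flanking reads still pseudoalign while the allele's effective
length stays short, inflating its rate; including the UTRs lowers the
TPM back toward truth while keeping it well above the 1-TPM background.
"""

import numpy as np

from allovax import build_index, utr_effect_experiment
from allovax.hla import TranscriptRecord
from allovax.simulate import (
    SimulationConfig,
    _decode,
    _random_seq,
    make_transcriptome,
    simulate_reads,
)

cfg = SimulationConfig(seed=5, n_reads=50_000)
reference, alleles, removal = make_transcriptome(10, 1, cfg)
keep = [r for r in reference if r.id not in set(removal)]

rng = np.random.default_rng(6)
full_alleles = [
    TranscriptRecord(
        id=a.id,
        sequence=_decode(_random_seq(rng, 150)) + a.sequence + _decode(_random_seq(rng, 250)),
        source="hla_allele",
        allele=a.allele,
    )
    for a in alleles
]
full_tx = keep + full_alleles
ids = [t.id for t in full_tx]
tpm = {t: 1e6 / len(ids) for t in ids}
reads, _ = simulate_reads(full_tx, tpm, cfg)

result = utr_effect_experiment(
    reads,
    build_index(keep + alleles, cfg.k, cfg.read_length),
    build_index(full_tx, cfg.k, cfg.read_length),
)
print(result.round(1))
print(
    "\nFor every allele the CDS+UTR index gives a lower TPM than the "
    "CDS-only index (ratio < 1), the direction observed when UTRs are "
    "added to an HLA-augmented index."
)
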