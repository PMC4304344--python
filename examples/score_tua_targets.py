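"""Optional external check: score sen-sRNA3 against the alpha-tubulin mRNAs.

The senescence locus's third small RNA targets a conserved region of the
Arabidopsis alpha-tubulin family; scored with the default penalty scheme the
TUA2, TUA4 and TUA6 sites come out at 4.0, 3.5 and 4.0.  The TAIR10 cDNA
sequences are not bundled (they must be fetched from arabidopsis.org), so
this script takes a FASTA of the three transcripts:

    python examples/score_tua_targets.py tua_mrnas.fa

and prints the best-scoring site per transcript with its predicted cleavage
position.
"""

import sys

from senescmir import io, predict_targets
from senescmir.sim import SEN_SRNA_SEQUENCES

if len(sys.argv) != 2:
    sys.exit(__doc__)

transcripts = io.read_fasta(sys.argv[1])
transcripts = {name: seq.replace("U", "T") for name, seq in transcripts.items()}
srna = SEN_SRNA_SEQUENCES["sen_sRNA3"]

hits = predict_targets(srna, transcripts, cutoff=4.0, srna_id="sen_sRNA3")
if not hits:
    print("no sites at score <= 4.0 — check that the FASTA holds full-length tubulin cDNAs")
for h in hits:
    print(f"{h.transcript_id}: score {h.score:.1f}  window {h.window_start + 1}-"
          f"{h.window_end}  cleavage at {h.cleavage_site}")
    print(f"  {h.srna_sequence}")
    print(f"  {h.pairing}")
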