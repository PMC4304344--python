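"""Score an sRNA against a transcriptome with the plant penalty scheme.

Penalties per sRNA position (mismatch 1.0, G:U 0.5, bulge 2.0, doubled at
positions 2-13); targets at score <= 4.0 are candidates, and each carries
the predicted cleavage site opposite sRNA position 10.
"""

import senescmir as sm
from senescmir import sim

cfg = sm.default_config(seed=1)
ref = sm.build_reference(cfg)
led = ref.ledger[ref.ledger.record == "mature"].set_index("name")
srna = led.loc["sen_sRNA3", "sequence"]

hits = sm.predict_targets(srna, ref.transcripts, cutoff=4.0, srna_id="sen_sRNA3")
for h in hits:
    print(f"{h.srna_id} -> {h.transcript_id}:{h.window_start + 1}-{h.window_end}  "
          f"score {h.score:.1f}  cleavage at {h.cleavage_site}")
    print(f"  sRNA 5'->3'  {h.srna_sequence}")
    print(f"               {h.pairing}   (| WC, o G:U, . mismatch, - bulge)")
# The planted site scores 0.0 (perfect complement); its cleavage position
# matches the truth ledger's expected PARE 5'-end.
print("ledger expected site:", int(led.loc["sen_sRNA3", "cleavage_pos"]))
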