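"""Generate the bundled synthetic study on disk.

Writes a 2x150 kb genome with structural-RNA annotations, a 20-transcript
transcriptome, eight raw small-RNA FASTQ libraries (leaf/silique x four
senescence stages), six PARE libraries, a known-miRNA catalog and the truth
ledger that records every planted sequence and its expected behaviour.
"""

from senescmir import sim

cfg = sim.default_config(seed=1, depth=100_000)
ref = sim.simulate_study(cfg, "example_out/study")

matures = ref.ledger[ref.ledger.record == "mature"]
print(f"wrote example_out/study: {len(cfg.srna_libraries)} sRNA + "
      f"{len(cfg.pare_libraries)} PARE libraries, {len(matures)} planted small RNAs")
print(matures[["name", "sequence", "length", "chrom", "start"]].to_string(index=False))
# Each row is one planted small RNA: its genomic placement and (in the full
# ledger) per-library expected read fractions and PARE cleavage site.
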