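"""uORF discovery, start-codon mutagenesis, and frameshift translation.

Builds a transcript whose 5'UTR carries two planted uORFs - one contained
in the UTR, one overlapping the main CDS out of frame (the configuration
of the Drosophila Xrp1 5'UTR) - rediscovers them, silences the overlapping
one by mutating its AUG to UAA, and shows how a 1-bp CDS deletion creates
a premature stop codon.
"""

from polyte import (
    apply_indel_and_translate,
    find_uorfs,
    generate_transcriptome,
    mutate_start_codon,
)

spec = [
    {"gene_id": "gene001", "kind": "contained"},
    {"gene_id": "gene001", "kind": "overlapping_out_of_frame"},
]
(transcript,), _ = generate_transcriptome(
    1, utr5_len_range=(50, 70), uorf_spec=spec, seed=8
)

print(f"transcript {transcript.transcript_id}: CDS starts at {transcript.cds_start}")
for i, u in enumerate(find_uorfs(transcript), start=1):
    end = u.stop_end if u.stop_end is not None else "no in-frame stop"
    print(f"  uORF{i}: start={u.start} stop_end={end} "
          f"frame_vs_cds={u.frame_vs_cds} class={u.overlap_class}")

uorf2 = find_uorfs(transcript)[1]
mutated = mutate_start_codon(transcript, uorf2, "UAA")
print(f"\nafter uORF2 AUG->UAA: {len(find_uorfs(mutated))} uORF(s) remain "
      "(the contained uORF1 only)")

out = apply_indel_and_translate("AUGAAACUAGGG", pos=3, del_len=1)
print(f"\n1-bp deletion in AUGAAACUAGGG: protein {out.protein!r}, "
      f"premature stop at codon {out.premature_stop_codon_index} - the "
      "frameshift truncates the protein.")
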