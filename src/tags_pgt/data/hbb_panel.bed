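# Reconstructed HBB target region (hg19); coordinates are a stand-in
# for the assay's supplementary primer tables, which are not shipped.
chr11	5246596	5248401	HBB
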