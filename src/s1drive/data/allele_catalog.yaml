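# SYNTHETIC placeholder allele catalog for the 7-site S1TPR/S1TP SNP panel.
#
# Each entry names one allele class by its haplotype structure and its
# exact 7-site state pattern (forward strand of the synthetic S1-g
# reference layout; site 7 is the C/A stop-gain site).  These entries are
# stand-ins keyed to the bundled data simulator's default lineages: the
# authoritative per-allele patterns for real accession panels must be
# supplied by the user as an edited copy of this file.  This file is
# data, not code — edit freely.
alleles:
  - name: "2-4"            # African-rice-like, complete three-gene structure
    structure: "A4-TPR-A6"
    pattern: "GACTGTC"
  - name: "2-1"            # two-gene TPR intermediate (placeholder pattern)
    structure: "A4-TPR"
    pattern: "GGCTGTC"
  - name: "1-3"            # Asian-rice-like one-gene TP structure
    structure: "TP"
    pattern: "TATCGGA"
  - name: "1-9"            # A4-TP intermediate (placeholder pattern)
    structure: "A4-TP"
    pattern: "GATCGGA"
  - name: "1-12"           # TP-A6 intermediate (placeholder pattern)
    structure: "TP-A6"
    pattern: "GACCGGA"
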