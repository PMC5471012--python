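# Actionable-mutation rules for the 26-gene NSCLC panel.
# One rule per entry; the engine applies rules in file order and the first
# match wins. Tiers: "standard" = approved first-line targeted therapy in the
# study's healthcare setting (EGFR inhibitors); everything else "emerging".
# KRAS is carried as its own tier flag downstream (eligibility reports are
# rendered with and without KRAS).
rules:
  - id: EGFR_exon19_deletion
    gene: EGFR
    kind: exon_event
    exon: 19
    event: deletion
    tier: standard
  - id: EGFR_exon20_insertion
    gene: EGFR
    kind: exon_event
    exon: 20
    event: insertion
    tier: emerging
  - id: EGFR_T790M
    gene: EGFR
    kind: named_protein_change
    change: T790M
    tier: emerging
  - id: EGFR_codon_719
    gene: EGFR
    kind: codon_set
    codons: [719]
    tier: standard
  - id: EGFR_codon_858
    gene: EGFR
    kind: codon_set
    codons: [858]
    tier: standard
  - id: EGFR_codon_861
    gene: EGFR
    kind: codon_set
    codons: [861]
    tier: standard
  - id: KRAS_codons_12_13_61
    gene: KRAS
    kind: codon_set
    codons: [12, 13, 61]
    tier: emerging
  - id: BRAF_codon_600
    gene: BRAF
    kind: codon_set
    codons: [600]
    tier: emerging
  # The fourth listed PIK3CA codon is a repetition of 1047 in the source
  # material; the set below is the de-duplicated reading. Override via a
  # custom rule file if another codon was intended.
  - id: PIK3CA_codons_542_545_1047
    gene: PIK3CA
    kind: codon_set
    codons: [542, 545, 1047]
    tier: emerging
  - id: NRAS_codons_12_13_61
    gene: NRAS
    kind: codon_set
    codons: [12, 13, 61]
    tier: emerging
  - id: ERBB2_exon20_insertion
    gene: ERBB2
    kind: exon_event
    exon: 20
    event: insertion
    tier: emerging
  - id: MAP2K1_codons_56_57
    gene: MAP2K1
    kind: codon_set
    codons: [56, 57]
    tier: emerging
  - id: AKT1_L52R
    gene: AKT1
    kind: named_protein_change
    change: L52R
    tier: emerging
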