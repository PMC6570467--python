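# EC prefixes excluded from the metabolic-gene set: enzymes whose substrates
# are proteins or nucleic acids rather than small molecules. Editable; a
# curated list can replace these defaults.
- prefix: "2.7.10"
  reason: protein-tyrosine kinases
- prefix: "2.7.11"
  reason: protein-serine/threonine kinases
- prefix: "2.7.12"
  reason: dual-specificity protein kinases
- prefix: "2.7.13"
  reason: protein-histidine kinases
- prefix: "3.4"
  reason: peptidases
- prefix: "2.7.7.6"
  reason: DNA-directed RNA polymerase
- prefix: "2.7.7.7"
  reason: DNA-directed DNA polymerase
- prefix: "2.7.7.49"
  reason: RNA-directed DNA polymerase (reverse transcriptase)
- prefix: "5.6.2"
  reason: topoisomerases and other nucleic-acid-altering enzymes
- prefix: "6.1.1"
  reason: amino-acid tRNA ligases
- prefix: "3.1.26"
  reason: endoribonucleases producing 5'-phosphomonoesters
- prefix: "3.1.27"
  reason: endoribonucleases producing 3'-phosphomonoesters
- prefix: "3.6.4"
  reason: ATPases acting on DNA/RNA and protein motors
- prefix: "2.3.2.27"
  reason: RING-type E3 ubiquitin transferase
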