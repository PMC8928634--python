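[
  {"name": "ip_exon_family", "pattern": "AAG[CT]CAGCNNNGCTGACTT",
   "note": "relaxed root covering the perfect-palindrome core and its one-mismatch exonic form"},
  {"name": "variant1", "pattern": "AAGTCAGCNNNGCTGACTT", "parent": "ip_exon_family",
   "note": "reconstructed: the unique self-reverse-complement (perfect palindrome) core"},
  {"name": "ip_exon_imperfect", "pattern": "AAGCCAGCNNNGCTGACTT", "parent": "ip_exon_family",
   "note": "the most abundant exon-resident imperfect palindrome (one arm mismatch)"},
  {"name": "variant8_reconstructed", "pattern": "AAAGATAAGCCAGCAAATCTGACTTCA", "parent": "ip_exon_family",
   "note": "reconstructed 27-nt unit back-translated from its published +0 peptide KDKPANLTS"},
  {"name": "composite60", "pattern": "AAAGATAAGTCAGCAGAGCTGAC[AT]TCCAGACCACTAAAGTGGTCAGTAACTAAAAGTTAT",
   "note": "60-nt composite repeat restricted to coding sequences; inserts 20 residues in frame"},
  {"name": "ip_intergenic", "pattern": "CAAACCAGTNNACTGGTTAG",
   "note": "the most abundant plastome imperfect palindrome (arms 9 bp, spacer 2, one mismatch)"},
  {"name": "interleave_partner", "pattern": "TAACTAAACTTC",
   "note": "conserved 12-mer interleaved with ip_intergenic in composite tandem clusters"},
  {"name": "interspersed_small", "pattern": "TAACTACTT",
   "note": "9-mer interspersed repeat forming one small 14-copy composite cluster"},
  {"name": "intron_cluster", "pattern": "TGGTTAGTAACTAAACTTCCAAACCAGTAAAC",
   "note": "32-mer with a 20-copy cluster in the atpA group I intron"}
]
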