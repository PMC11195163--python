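"""Reference sequences used throughout the examples and tests.

These are the study system's printed sequences: the 68-residue
*S. cerevisiae* SERF protein and the 29-nt bulged stem-loop fragment of the
HIV-1 TAR RNA (nucleotides 19-45 of the element).
"""

from .charge import ProteinSequence, RNASequence

#: S. cerevisiae SERF (YDL085C-A), 68 residues.
SERF_YEAST = ProteinSequence(
    "MARGNQRDLARQKNLKKQKDMAKNQKKSGDPKKRMESDAE"
    "ILRQKQAAADARREAEKLEKLKAEKTRR",
    name="SERF (S. cerevisiae)",
)

#: HIV-1 TAR bulged stem-loop fragment, 29 nt.
TAR_HIV1 = RNASequence("GGCAGAUCUGAGCCUGGGAGCUCUCUGCC", name="HIV-1 TAR (29 nt)")
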