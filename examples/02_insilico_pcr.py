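"""Identify a marker's amplicon in a reference sequence by in-silico PCR.

Both primers are scanned against the reference on both strands (ungapped,
allowing up to 10 nt of primer shortfall at >= 90% identity), forward/reverse
hits are paired into candidate fragments, and a decision tree keeps a single
fragment whose adjusted length falls within 6 bp of the species' observed
allele-length range.
"""
import numpy as np

import orthosat as o
from orthosat import epcr
from orthosat.types import revcomp

rng = np.random.default_rng(11)
bases = np.array(list("ACGT"))
rand = lambda n: "".join(rng.choice(bases, size=n))

forward_site = rand(22)
reverse_site = rand(22)
amplicon = forward_site + rand(80) + "GATA" * 12 + rand(28) + reverse_site
reference = rand(150) + amplicon + rand(150)

pp = o.PrimerPair("demo", forward=forward_site, reverse=revcomp(reverse_site))
observed = o.LengthRange(len(amplicon) - 8, len(amplicon) + 8, species="human")

decision = epcr.run_epcr(pp, reference, observed)
print("outcome:", decision.outcome)
frag = decision.chosen_fragment
print("raw length:", frag.raw_length, "adjusted:", frag.adjusted_length)
print("fragment starts at reference position", frag.start)
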