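"""The Bayesian mapping-quality model on hand-built hit configurations.

Likelihood of a hit with identity s: C * exp(-lambda * (100 - s)); the
posterior over a read's validated hits is PHRED-scaled, capped at 60, and
forced to 0 when two or more best hits tie.
"""

from qgmap import MappingQualityModel, mapping_quality
from qgmap.validation import ValidatedHit


def hit(start, k, rlen=100):
    return ValidatedHit(read_id=0, strand="+", chrom="chr1",
                        ref_start=start, ref_end=start + rlen, k=k, read_len=rlen)


model = MappingQualityModel()  # lambda=1, C=1, cap 60

print("single hit:                ", mapping_quality([hit(0, 0)], model))
print("two perfect hits (tied):   ", mapping_quality([hit(0, 0), hit(500, 0)], model))
print("s=100 vs s=95:             ", mapping_quality([hit(0, 0), hit(500, 5)], model))
print("s=100 vs s=90:             ", mapping_quality([hit(0, 0), hit(500, 10)], model))
# A unique hit has posterior 1, so it reports the cap (60). Tied best hits
# are ambiguous and report 0. A 5-point identity gap gives posterior
# 1/(1+e^-5) ~ 0.9933 -> floor(-10*log10(1-0.9933)) = 21.
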