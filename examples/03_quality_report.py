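"""Video quality scoring: a clean recording versus an artifacted one.

Renders the same field of fluorescent blobs twice — once clean, once with
photobleaching, tissue drift and detector noise injected — and scores both.
The five subscores (contrast CR, noise NR, photobleaching PB, saturation
SAT, signal variation SV) are each in [0, 1] with 1 = no artifact; the
composite is their mean. The artifacted copy must score lower.
"""

from ivtk import gen_quality_pair, quality_report

clean, artifacted = gen_quality_pair(seed=0)

for name, stack in (("clean", clean), ("artifacted", artifacted)):
    rep = quality_report(stack)
    subs = "  ".join(f"{k}={v:.2f}" for k, v in rep.goodness.items())
    print(f"{name:11s} composite {rep.composite:.3f}   ({subs})")
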