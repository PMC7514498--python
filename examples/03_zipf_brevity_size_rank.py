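"""Zipf's law, the brevity law, and the size-rank law that links them.

The generator couples type frequency and mean duration through
ell_r = ell_min + (alpha/lambda)·log r, so all three laws should be
recovered jointly: the fitted size-rank slope theta should match
alpha/lambda from the other two fits.
"""

from speechlaws import SynthSpec, analyze_brevity, analyze_size_rank, analyze_zipf, generate_corpus

spec = SynthSpec(seed=5, zipf_alpha=1.42, brevity_lambda=23.8, vocab_size=100)
corpus = generate_corpus(spec, 50_000)

zipf = analyze_zipf(corpus)
brevity = analyze_brevity(corpus, level="word")
size_rank = analyze_size_rank(zipf, brevity, unit="duration")

dur = brevity.fits["duration"]
print(f"Zipf alpha      : {zipf.word_fit.alpha:.3f}   (generating 1.42, xmin={zipf.word_fit.xmin})")
print(f"brevity lambda  : {dur.lambda_rate:.2f}    (generating 23.8 1/s)")
print(f"Spearman rho    : {dur.spearman_rho:.3f}  (p={dur.spearman_p:.2e})")
print(f"lambda_D        : {brevity.lambda_D}")
print(f"size-rank theta : {size_rank.theta:.4f}  predicted alpha/lambda = "
      f"{size_rank.theta_predicted:.4f}")
# theta and alpha/lambda agree within a few percent: the size-rank law is
# the deterministic consequence of Zipf + brevity.  lambda_D in (0, 1]
# measures distance from optimal non-singular coding in symbolic units.
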