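"""One-shot two-level analysis, exactly as the pipeline CLI runs it.

Level 1 separates Indica from Sativa on all 300 spectra; level 2 drops the
Indica class and separates the four Sativa varieties.  Both levels are
scored by 7-fold cross-validated confusion matrices with Fisher's exact
probability of the table arising by chance."""

import trichospec as ts

report = ts.run(ts.PipelineConfig(seed=1))

for name in ("genetics", "variety"):
    res = getattr(report, name)
    print(f"--- {name} model: {res.n_pred} predictive + {res.n_orth} orthogonal ---")
    print(f"R2X cum {100 * res.model.r2x_cum:.1f}%   Q2 {res.cv.q2:.3f}")
    print(res.matrix.to_text())
    print()
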