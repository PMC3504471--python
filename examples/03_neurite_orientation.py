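"""Neurite-orientation analysis on synthetic Golgi-like images.

Simulates two image fields with different orientation coherence — a
"treated" field with tightly radial processes (kappa = 2.08) and a
"control" field with a broader spread (kappa = 1.41) — runs the full
pipeline (threshold -> skeletonize -> line-segment extraction -> polar
angles -> axial Von Mises fit with bootstrap CI) on each, and compares the
fitted concentrations.
"""

from cortexclock import (
    GolgiSimSpec,
    compare_regions,
    extract_segments,
    fit_with_ci,
    segment_polar_angles,
    skeletonize,
)
from cortexclock.synthetic import gen_golgi_image


def analyze(label: str, kappa: float, seed: int):
    spec = GolgiSimSpec(
        image_size=(1024, 1024), n_segments=600, mu_deg=0.0, kappa=kappa, seed=seed
    )
    image, _ = gen_golgi_image(spec)
    skeleton = skeletonize(image)
    segments = extract_segments(skeleton, min_length_px=10, max_deviation_px=2.0)
    sample = segment_polar_angles(segments, region_label=label)
    fit = fit_with_ci(sample, n_boot=1000, seed=seed + 1)
    print(
        f"{label}: generating kappa={kappa:.2f} -> fitted kappa={fit.kappa:.2f} "
        f"(95% CI {fit.ci_95[0]:.2f}-{fit.ci_95[1]:.2f}, n={fit.n} segments, "
        f"mu={fit.mu_deg:.1f} deg from radial)"
    )
    return fit


treated = analyze("treated", kappa=2.08, seed=7)
control = analyze("control", kappa=1.41, seed=9)

cmp = compare_regions(treated, control)
print(
    f"kappa difference {cmp['kappa_diff']:.2f}; "
    f"95% CIs disjoint: {cmp['ci_disjoint']} "
    "(disjoint CIs = the two fields' orientation coherence differs)"
)
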