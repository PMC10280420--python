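"""Run the ten-attack robustness bench on a phantom.

Each row attacks the watermarked slice (noise, compression, filtering,
enhancement), re-extracts the watermark and scores it against the original
(PSNR / SSIM / NC).  The no-attack row is exact (NC = 1); noise and
filtering degrade NC the way severity suggests.
"""

import niftimark as nm

vol = nm.make_phantom_volume(512, 1, seed=31)
logo = nm.make_watermark(64)
cfg = nm.EmbedConfig(mu=0.01, key=nm.default_key(64),
                     slice=nm.SliceRef(axis=2, index=0))

table = nm.run_robustness_bench(vol, logo, cfg,
                                nm.default_attack_suite(seed=2))

print(table.drop(columns=["extracted"]).to_string(
    index=False, float_format=lambda v: f"{v:.4f}"))
print("\nNC = 1 on the 'none' row confirms exact attack-free recovery;")
print("lower NC/SSIM rows show which degradations hurt the watermark most.")
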