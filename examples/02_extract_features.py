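"""Extract the full 457-variable feature record from one canopy image.

Runs stretch -> mask -> 35 transforms -> 140 color moments + 315
co-occurrence texture statistics, plus the Location and Time covariates.
"""

import datetime as dt

import canopyfeat as cf

scene = cf.generate_scene(seed=1)
meta = cf.ImageMetadata(
    image_id="demo",
    location=1,
    planting_date=dt.date(2016, 5, 20),
    measuring_date=dt.date(2016, 6, 21),
)
record = cf.extract_features(scene.image, meta)

print(f"valid record        : {record['valid']}")
print(f"predictor columns   : {len(cf.feature_columns())}")
print(f"  color features    : {len(cf.color_feature_names())}")
print(f"  texture features  : {len(cf.texture_feature_names())}")
print(f"  covariates        : location={record['location']}, time={record['time']} days")
print(f"raw-channel view    : {len(cf.rgb_lnt_columns())} columns")
for name in ("G_mu", "G_sigma", "NGRD_mu", "G_ENT", "G_CON", "TGI_ASM"):
    print(f"  {name:<10}= {record[name]:.4f}")
# G_mu is the mean stretched green intensity over plant pixels; G_ENT and
# G_CON are the direction-averaged co-occurrence entropy and contrast of the
# green channel — higher values mean a more complex canopy texture.
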