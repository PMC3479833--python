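"""Render a road scene and compare the three contrast-reduction models.

Builds a small procedural road frame, applies fog (distance-dependent),
anti-fog (reversed gradient) and a contrast-matched uniform reduction,
and prints each condition's global RMS contrast.  Fog and the matched
uniform plane end up with the same *global* contrast while distributing
it very differently over depth — the core manipulation of the pipeline.
"""

from fogspeed import optics, scene

spec = scene.SceneSpec(width_px=160, height_px=120, horizon_row=40, seed=1)
frame = scene.make_road_scene(spec)
cal = optics.CalibrationCurve.identity()

clear = optics.rms_contrast(frame, cal, label="clear")
print(f"clear visibility      RMS contrast = {clear.rms_contrast:.3f}")

fog = optics.FogParams(density_f=0.3)  # MVR = ln(20)/0.3 ~ 10 m
foggy = optics.apply_condition(frame, fog)
fog_report = optics.rms_contrast(foggy, cal, label="fog")
print(
    f"fog f=0.3 /m          RMS contrast = {fog_report.rms_contrast:.3f}"
    f"  (MVR = {optics.mvr_from_density(0.3):.1f} m)"
)

opacity = optics.match_uniform_opacity(frame, cal, fog_report.rms_contrast)
uniform = optics.apply_condition(frame, optics.UniformParams(opacity))
uni_report = optics.rms_contrast(uniform, cal, label="uniform")
print(f"uniform opacity={opacity:.3f} RMS contrast = {uni_report.rms_contrast:.3f}")

af = optics.match_antifog_density(frame, cal, fog_report.rms_contrast)
antifog = optics.apply_condition(frame, optics.AntiFogParams(af))
af_report = optics.rms_contrast(antifog, cal, label="antifog")
print(f"anti-fog af={af:.3f} /m  RMS contrast = {af_report.rms_contrast:.3f}")

print(
    "\nThe three degraded conditions share the same global contrast; only the"
    "\nspatial (depth) distribution of that contrast differs."
)
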