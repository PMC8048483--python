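# Reduced scenario-2 configuration: 6x6 canopy + 4 shade-blind competitors.
# Any field of ScenarioConfig may appear here; omitted fields keep their
# defaults (full 10x10 / 2.5 cm stand, 16 competitors, 44 days).
scenario: 2
hyponasty_rate: 10.0
n_stands: 2
days: 44
nx: 6
ny: 6
n_competitors: 4
central_canopy: 4
central_competitors: 4
cover_resolution: 50
master_seed: 11
source:
  par_intensity: 220.0
  r_fr_ratio: 2.3
  angular_model: overcast-diffuse
  n_rays: 2000
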