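schema: gantryclear-machine/1
units: mm
nozzle_face_to_iso: 420.0
ers_face_to_iso: 270.0
snout_radius: 160.0
snout_length: 350.0
head_casing_radius: 450.0
head_casing_depth: 600.0
touch_guard_standoff: 60.0
couch_tops:
  civco:
    length: 2000.0
    width: 530.0
    thickness: 70.0
  orfit:
    length: 1500.0
    width: 530.0
    thickness: 50.0
arm_link_lengths:
- 700.0
- 1500.0
- 1250.0
- 250.0
base_position:
- 900.0
- -1400.0
- -1300.0
kv_source_positions:
- - 1400.0
  - 1000.0
  - 1700.0
- - -1400.0
  - 1000.0
  - 1700.0
kv_detector_centers:
- - -1260.0
  - -900.0
  - -1530.0
- - 1260.0
  - -900.0
  - -1530.0
longitudinal_safety_margin: 10.0
chord_tolerance: 5.0
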