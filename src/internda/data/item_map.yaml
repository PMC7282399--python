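# Default 37-item map: 31 five-point + 6 three-point items across six domains.
# The item->domain allocation is a package convention (the instrument's true
# layout is not reproduced here); override with your own map config.
version: default-37
items:
- item_id: cog01
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog02
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog03
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog04
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog05
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog06
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog07
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog08
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog09
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog10
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog11
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: cog12
  domain: cognitive
  scale_points: 5
  admin_mode: direct
- item_id: fm01
  domain: fine_motor
  scale_points: 5
  admin_mode: direct
- item_id: fm02
  domain: fine_motor
  scale_points: 5
  admin_mode: direct
- item_id: fm03
  domain: fine_motor
  scale_points: 5
  admin_mode: direct
- item_id: fm04
  domain: fine_motor
  scale_points: 5
  admin_mode: direct
- item_id: fm05
  domain: fine_motor
  scale_points: 5
  admin_mode: direct
- item_id: gm01
  domain: gross_motor
  scale_points: 5
  admin_mode: observation
- item_id: gm02
  domain: gross_motor
  scale_points: 5
  admin_mode: observation
- item_id: gm03
  domain: gross_motor
  scale_points: 5
  admin_mode: observation
- item_id: gm04
  domain: gross_motor
  scale_points: 5
  admin_mode: observation
- item_id: gm05
  domain: gross_motor
  scale_points: 5
  admin_mode: observation
- item_id: lan01
  domain: language
  scale_points: 5
  admin_mode: direct
- item_id: lan02
  domain: language
  scale_points: 5
  admin_mode: direct
- item_id: lan03
  domain: language
  scale_points: 5
  admin_mode: direct
- item_id: lan04
  domain: language
  scale_points: 5
  admin_mode: direct
- item_id: lan05
  domain: language
  scale_points: 5
  admin_mode: direct
- item_id: lan06
  domain: language
  scale_points: 5
  admin_mode: direct
- item_id: lan07
  domain: language
  scale_points: 5
  admin_mode: direct
- item_id: pb01
  domain: positive_behaviour
  scale_points: 5
  admin_mode: observation
- item_id: pb02
  domain: positive_behaviour
  scale_points: 5
  admin_mode: observation
- item_id: pb03
  domain: positive_behaviour
  scale_points: 3
  admin_mode: caregiver_report
- item_id: pb04
  domain: positive_behaviour
  scale_points: 3
  admin_mode: caregiver_report
- item_id: nb01
  domain: negative_behaviour
  scale_points: 3
  admin_mode: caregiver_report
- item_id: nb02
  domain: negative_behaviour
  scale_points: 3
  admin_mode: caregiver_report
- item_id: nb03
  domain: negative_behaviour
  scale_points: 3
  admin_mode: caregiver_report
- item_id: nb04
  domain: negative_behaviour
  scale_points: 3
  admin_mode: caregiver_report
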