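latents:
- name: ses
  indicators:
  - age_father
  - age_mother
  - edu_father
  - edu_mother
  - income_mother
  - income_father
- name: lifestyle
  indicators:
  - sleep
  - physical_activity
  - screen_time
  - pocket_money
- name: healthy_food
  indicators:
  - fruits
  - vegetables
  - whole_grains
- name: unhealthy_food
  indicators:
  - snacks
  - fast_food
  - soft_drink
  - sweets
observed_outcomes:
- bmi
- body_fat
controls:
- parent_bmi
- parent_body_fat
paths:
- source: ses
  target: healthy_food
  role: structural
- source: ses
  target: unhealthy_food
  role: structural
- source: ses
  target: lifestyle
  role: structural
- source: ses
  target: bmi
  role: structural
- source: ses
  target: body_fat
  role: structural
- source: lifestyle
  target: healthy_food
  role: structural
- source: lifestyle
  target: unhealthy_food
  role: structural
- source: lifestyle
  target: bmi
  role: structural
- source: lifestyle
  target: body_fat
  role: structural
- source: healthy_food
  target: bmi
  role: structural
- source: healthy_food
  target: body_fat
  role: structural
- source: unhealthy_food
  target: bmi
  role: structural
- source: unhealthy_food
  target: body_fat
  role: structural
- source: parent_bmi
  target: bmi
  role: control
- source: parent_body_fat
  target: body_fat
  role: control
group_variable: gender
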