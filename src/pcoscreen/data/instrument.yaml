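# Default definition of the 31-item screening instrument.
#
# Four criterion groups: 11 physical items (menstrual and lifestyle
# symptoms of PCOS), the 10 Kessler K10 psychological-distress items,
# 5 social-phobia items and 5 body-image-dissatisfaction items.
# Answer levels are ordered from least to most symptomatic; the published
# instrument states the question topics and example phrasings but not the
# complete level vocabularies, so these five-level sets are a declared,
# configurable default.
criteria:
  - id: C11
    group: physical
    text: Regularity of periods
    levels: [very regular, regular, occasionally irregular, fairly irregular, quite irregular]
  - id: C12
    group: physical
    text: Length of the menstrual cycle
    levels: [21-27 days, 28-35 days, 36-45 days, 46-90 days, more than 90 days]
  - id: C13
    group: physical
    text: Duration of the flow
    levels: [3-5 days, 5-7 days, 1-3 days, more than 7 days, less than a day]
  - id: C14
    group: physical
    text: Number of pads used per day
    levels: [1-2, 2-3, 3-4, 4-5, more than 5]
  - id: C15
    group: physical
    text: During cycle, tendency to grow dark, coarse hair on chest and chin
    levels: [never, rarely, sometimes, often, always]
  - id: C16
    group: physical
    text: Weight gain
    levels: [none, slight, moderate, high, very high]
  - id: C17
    group: physical
    text: Eating junk food
    levels: [never, rarely, sometimes, often, always]
  - id: C18
    group: physical
    text: Meal times and eating pattern
    levels: [very regular, regular, somewhat irregular, irregular, very irregular]
  - id: C19
    group: physical
    text: Sleep schedule / sleep pattern
    levels: [very regular, regular, somewhat irregular, irregular, very irregular]
  - id: C110
    group: physical
    text: Family history of diabetes
    levels: [no history, distant relative, grandparent, one parent, both parents]
  - id: C111
    group: physical
    text: Family history of hypertension
    levels: [no history, distant relative, grandparent, one parent, both parents]
  - id: C21
    group: anxiety_depression
    text: Feel tired for no good reason
    levels: &k10 [none of the time, a little of the time, some of the time, most of the time, all of the time]
  - id: C22
    group: anxiety_depression
    text: Feel nervous
    levels: *k10
  - id: C23
    group: anxiety_depression
    text: Feel so nervous that nothing could calm you down
    levels: *k10
  - id: C24
    group: anxiety_depression
    text: Feel hopeless
    levels: *k10
  - id: C25
    group: anxiety_depression
    text: Feel restless or fidgety
    levels: *k10
  - id: C26
    group: anxiety_depression
    text: Feel so restless that you could not sit still
    levels: *k10
  - id: C27
    group: anxiety_depression
    text: Feel depressed
    levels: *k10
  - id: C28
    group: anxiety_depression
    text: Feel everything was an effort
    levels: *k10
  - id: C29
    group: anxiety_depression
    text: Feel so sad that nothing could cheer you up
    levels: *k10
  - id: C210
    group: anxiety_depression
    text: Feel worthless
    levels: *k10
  - id: C31
    group: social_phobia
    text: Intense and persistent fear that others might evaluate you
    levels: &freq [never, rarely, sometimes, most of the times, always]
  - id: C32
    group: social_phobia
    text: Fear of being humiliated in social situations
    levels: *freq
  - id: C33
    group: social_phobia
    text: Feeling extremely self-conscious
    levels: *freq
  - id: C34
    group: social_phobia
    text: Fear that others will notice blushing or sweating
    levels: *freq
  - id: C35
    group: social_phobia
    text: Try hard to avoid social situations or interaction
    levels: *freq
  - id: C41
    group: body_image
    text: Spend a lot of time worrying about their appearance
    levels: *freq
  - id: C42
    group: body_image
    text: Experience dissatisfaction with their appearance
    levels: *freq
  - id: C43
    group: body_image
    text: Avoid wearing certain clothes because they may look fat
    levels: *freq
  - id: C44
    group: body_image
    text: Compare their appearance with others and feel low
    levels: *freq
  - id: C45
    group: body_image
    text: Dissatisfaction and self-consciousness of appearance interferes with social activities
    levels: *freq
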