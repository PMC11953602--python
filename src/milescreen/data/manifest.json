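{
  "files": {
    "constants.json": "1b1d65ca5ed8f733f98bdfd8f97f207135d1f14a86836d21c0d7830a3984c26a",
    "table_acceptance.csv": "1ad1168f6ac2b0b1394a2db1b3b6b99a0d03983f99a8f39a1cfaae94e9abd2a6",
    "table_alarms_by_month.csv": "bc0c85608630c4b7bb6e654c0b7af4a18883f815072715bb5f3e4202c781259f",
    "table_cohort.csv": "1832e3a8e254240319cdebfb8163b3774d585a6ab9eb937e778d7dfda94cf042",
    "table_control.csv": "802d77325bb0297bc9fb31397ea891d0ed6c55ddf01713574b092d2b1364baff",
    "table_decline_reasons.csv": "d54e4907e654f99085e2ac4b55c91e81a0d3d33c0a196ad12fc0ee578cf30c53",
    "table_gender.csv": "906b41c30028cebc2545515c2c0dd0e2d1cf8cf92161f82d758e69684204c2de",
    "table_suggestions.csv": "1b700314699f93960b1becd24e1fdb65d8991ae4422c805d261e9ef56a58d934"
  }
}
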