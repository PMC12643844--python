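# Meaning-in-life seed keywords (questionnaire-derived terms + synonyms)
meaning
purpose
value
faith
ideal
aspiration
future
pursuit
quest
seek
establish
presence
exploration
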