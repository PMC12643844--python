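# Sleep-context seed keywords (sleep-quality-index-derived terms + synonyms)
insomnia
staying up late
having many dreams
nightmare
waking up startled
sleepy
early morning
having a dream
unable to fall asleep
sleep
easy to wake up
dreaming about
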