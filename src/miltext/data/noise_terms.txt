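# Stand-in noise/stop list for corpus cleaning (the full curated list used
# in production is user-supplied; any one-term-per-line file works).
http
https
www.
click the link
discount
coupon
free shipping
follow and repost
lottery
giveaway
super-topic
advertisement
promo code
limited offer
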