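domain,package
facebook.com,com.facebook.katana
m.facebook.com,com.facebook.katana
messenger.com,com.facebook.orca
instagram.com,com.instagram.android
twitter.com,com.twitter.android
x.com,com.twitter.android
mobile.twitter.com,com.twitter.android
reddit.com,com.reddit.frontpage
old.reddit.com,com.reddit.frontpage
tiktok.com,com.zhiliaoapp.musically
tumblr.com,com.tumblr
linkedin.com,com.linkedin.android
pinterest.com,com.pinterest
web.whatsapp.com,com.whatsapp
web.telegram.org,org.telegram.messenger
discord.com,com.discord
grindr.com,com.grindrapp.android
tinder.com,com.tinder
adam4adam.com,com.adam4adam.radar
scruff.com,com.scruff.app
bumble.com,com.bumble.app
okcupid.com,com.okcupid.okcupid
match.com,com.match.android.matchmobile
hornet.com,com.hornet.android
jackd.mobi,com.jackd.android
feeld.co,com.feeld.app
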