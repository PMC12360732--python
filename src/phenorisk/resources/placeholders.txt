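Enter message
Say something
Type a message
Search
Search here
Write a comment
Add a comment
Send a message
Message
Aa
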