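same as before
same as the last clip
in this clip
in the clip
in this scene
in the scene
in this video
in the video
this clip
the clip
this scene
the scene
the camera
the screen
the video
the footage
the shot
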